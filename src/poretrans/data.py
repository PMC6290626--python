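"""Reference exponents and experimental records from the literature.

``OBSERVED_EXPONENTS`` holds the scaling exponents extracted from
full-scale Langevin simulations of this system (500+ runs per state
point, chains up to 379 transported monomers, explicit ions): the three
regime exponents alpha_UB, alpha_SD(T), alpha_SD(I), the peak
delta_SD(T), the static size exponents nu_s0 (tethered chain) and nu_b0
(free-chain blobs) and the subdiffusion exponent gamma_p, for the
monovalent (Z=1) and divalent (Z=2) salt cases.  They are the inputs of
the exponent-inversion chain; the derived set (nu_s, q, z_p, rho, eta)
is recomputed by :mod:`poretrans.theory`, with the two-decimal reported
values in ``DERIVED_EXPONENTS_REPORTED`` for cross-checking.

``EXPERIMENTS`` lists published solid-state-nanopore DNA translocation
measurements used for the simulation-to-experiment comparison.
"""

from .units import ExperimentRecord

SALT_CASES = ("monovalent", "divalent")

OBSERVED_EXPONENTS = {
    "monovalent": dict(alpha_UB=2.39, alpha_SDT=1.05, alpha_SDI=1.35,
                       delta_SDT=1.65, nu_s0=0.71, nu_b0=0.68, gamma_p=0.78),
    "divalent": dict(alpha_UB=2.61, alpha_SDT=1.06, alpha_SDI=1.50,
                     delta_SDT=1.77, nu_s0=0.57, nu_b0=0.55, gamma_p=0.75),
}

DERIVED_EXPONENTS_REPORTED = {
    "monovalent": dict(nu_s=0.35, q=0.86, z_p=5.06, rho=1.50, eta=1.32),
    "divalent": dict(nu_s=0.50, q=0.88, z_p=4.88, rho=1.43, eta=1.14),
}

#: z_p from the consistency relation gamma_p = (1+nu_s)/(z_p nu_s),
#: as reported alongside the inversion chain
CONSISTENCY_ZP_REPORTED = {"monovalent": 4.95, "divalent": 4.00}

#: z_p = 2/nu_s0 predicted for a head-pulled chain in free solution
PULLED_CHAIN_ZP_REPORTED = {"monovalent": 2.82, "divalent": 3.51}

#: q = (1-nu_b0)/(1+nu_b0) from the static blob exponent
Q_FROM_NU_B0_REPORTED = {"monovalent": 0.19, "divalent": 0.29}

EXPERIMENTS = [
    ExperimentRecord(label="pBR322 4.4 kbp, 1.6 M KCl",
                     contour_bp=4400.0, tau_seconds=110e-6,
                     field_mV_per_nm=8.0, salt="monovalent"),
    ExperimentRecord(label="pBR322 4.4 kbp, 1.6 M KCl + 100 mM MgCl2",
                     contour_bp=4400.0, tau_seconds=145e-6,
                     field_mV_per_nm=8.0, salt="divalent"),
    ExperimentRecord(label="lambda-DNA 48.8 kbp, 1 M KCl",
                     contour_bp=48800.0, tau_seconds=0.38e-3,
                     field_mV_per_nm=30.0, salt="monovalent"),
    ExperimentRecord(label="lambda-DNA 48.8 kbp, 1 M MgCl2",
                     contour_bp=48800.0, tau_seconds=1.31e-3,
                     field_mV_per_nm=30.0, salt="divalent"),
]
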