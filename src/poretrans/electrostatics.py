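"""Classical Ewald summation (reference electrostatics solver).

The production solver is the damped shifted-force (DSF) real-space sum in
`_kernels.compute_forces`; this module provides the conventional Ewald
decomposition (real + reciprocal + self, tinfoil boundary) as the
independent reference against which the DSF approximation is validated on
small ion clusters.  Written in vectorised numpy; intended for systems of
at most a few hundred charges.

Energies are in kBT with the pair energy ``lambda_B * qi * qj / r``.
"""

from __future__ import annotations

import math

import numpy as np


def _minimum_image(d, box):
    return d - box * np.round(d / box)


def ewald_energy_forces(positions, charges, box, lambda_B,
                        alpha=None, r_cut=None, accuracy=1e-6):
    """Ewald energy and analytic forces for a periodic charge set.

    Parameters
    ----------
    positions : (n, 3) array
    charges : (n,) array
    box : (3,) array, orthorhombic sides
    lambda_B : Bjerrum length (coupling prefactor)
    alpha : splitting parameter; default tuned from ``r_cut`` and accuracy
    r_cut : real-space cutoff, default ``0.49 * min(box)``
    accuracy : target relative truncation error of both sums

    Returns
    -------
    (energy, forces) with forces of shape (n, 3)
    """
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    box = np.asarray(box, dtype=float)
    n = pos.shape[0]
    V = float(np.prod(box))

    if r_cut is None:
        r_cut = 0.49 * float(box.min())
    if alpha is None:
        # erfc(alpha * r_cut) ~ accuracy
        alpha = math.sqrt(-math.log(accuracy)) / r_cut

    forces = np.zeros((n, 3))

    # --- real-space sum (minimum image; r_cut < box/2) -----------------------
    d = pos[:, None, :] - pos[None, :, :]
    d = _minimum_image(d, box)
    r = np.sqrt((d ** 2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    rr = r[iu]
    mask = rr < r_cut
    qq = (q[:, None] * q[None, :])[iu]
    erfc_r = np.zeros_like(rr)
    erfc_r[mask] = np.array([math.erfc(alpha * x) for x in rr[mask]])
    e_real = lambda_B * np.sum(np.where(mask, qq * erfc_r / np.where(rr > 0, rr, 1.0), 0.0))

    # real-space forces
    fmag = np.zeros_like(rr)
    rm = rr[mask]
    fmag[mask] = (erfc_r[mask] / rm ** 2
                  + (2.0 * alpha / math.sqrt(math.pi))
                  * np.exp(-(alpha * rm) ** 2) / rm)
    fr = lambda_B * np.where(mask, qq * fmag / np.where(rr > 0, rr, 1.0), 0.0)
    fvec = fr[:, None] * d[iu]
    np.add.at(forces, iu[0], fvec)
    np.add.at(forces, iu[1], -fvec)

    # --- reciprocal-space sum ------------------------------------------------
    # cutoff k_max with exp(-k^2 / 4 alpha^2) / k^2 ~ accuracy
    kmax_mag = 2.0 * alpha * math.sqrt(-math.log(accuracy))
    nmax = np.maximum(1, np.ceil(kmax_mag * box / (2.0 * math.pi)).astype(int))
    gx = np.arange(-nmax[0], nmax[0] + 1)
    gy = np.arange(-nmax[1], nmax[1] + 1)
    gz = np.arange(-nmax[2], nmax[2] + 1)
    GX, GY, GZ = np.meshgrid(gx, gy, gz, indexing="ij")
    G = np.stack([GX.ravel(), GY.ravel(), GZ.ravel()], axis=1)
    G = G[np.any(G != 0, axis=1)]
    k = 2.0 * math.pi * G / box[None, :]
    k2 = (k ** 2).sum(axis=1)
    keep = k2 <= kmax_mag ** 2
    k = k[keep]
    k2 = k2[keep]

    phase = pos @ k.T                        # (n, nk)
    c = np.cos(phase)
    s = np.sin(phase)
    Sc = q @ c
    Ss = q @ s
    ak = np.exp(-k2 / (4.0 * alpha ** 2)) / k2
    e_recip = lambda_B * (2.0 * math.pi / V) * np.sum(ak * (Sc ** 2 + Ss ** 2))

    # reciprocal forces: F_i = lambda_B (4 pi / V) q_i sum_k k ak (sin_i Sc - cos_i Ss)
    coef = (4.0 * math.pi / V) * lambda_B
    w = ak[None, :] * (s * Sc[None, :] - c * Ss[None, :])   # (n, nk)
    forces += coef * q[:, None] * (w @ k)

    # --- self term -----------------------------------------------------------
    e_self = -lambda_B * alpha / math.sqrt(math.pi) * np.sum(q ** 2)

    return float(e_real + e_recip + e_self), forces


def dsf_energy_forces(positions, charges, box, lambda_B, alpha, r_cut):
    """Damped shifted-force Coulomb sum (numpy mirror of the kernel)."""
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    box = np.asarray(box, dtype=float)
    n = pos.shape[0]
    forces = np.zeros((n, 3))

    erfc_rc = math.erfc(alpha * r_cut)
    u_shift = erfc_rc / r_cut
    f_shift = (erfc_rc / r_cut ** 2
               + (2.0 * alpha / math.sqrt(math.pi))
               * math.exp(-(alpha * r_cut) ** 2) / r_cut)
    # Wolf self term
    e_self = -lambda_B * (0.5 * u_shift
                          + alpha / math.sqrt(math.pi)) * float(np.sum(q ** 2))

    d = pos[:, None, :] - pos[None, :, :]
    d = _minimum_image(d, box)
    r = np.sqrt((d ** 2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    rr = r[iu]
    qq = (q[:, None] * q[None, :])[iu]
    mask = (rr < r_cut) & (qq != 0.0)
    rm = np.where(mask, rr, 1.0)
    erfc_r = np.array([math.erfc(alpha * x) for x in rm])
    u = lambda_B * qq * (erfc_r / rm - u_shift + f_shift * (rm - r_cut))
    energy = float(np.sum(np.where(mask, u, 0.0))) + e_self
    fmag = lambda_B * qq * (erfc_r / rm ** 2
                            + (2.0 * alpha / math.sqrt(math.pi))
                            * np.exp(-(alpha * rm) ** 2) / rm
                            - f_shift)
    fr = np.where(mask, fmag / rm, 0.0)
    fvec = fr[:, None] * d[iu]
    np.add.at(forces, iu[0], fvec)
    np.add.at(forces, iu[1], -fvec)
    return energy, forces
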