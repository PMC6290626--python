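"""Tension-propagation scaling theory of driven polymer translocation.

The mean translocation time of an ``N``-monomer chain driven by a force
``f`` inside the pore obeys ``<tau> ~ N^alpha f^-delta`` with exponents
that change across four force regimes:

====================  =======================  ==============
regime                alpha                    delta
====================  =======================  ==============
UB   (unbiased)       2 + nu_s z_p (1-gamma_p)  0
WD   (weakly driven)  1 + nu_s z_p (1-gamma_p)  1
SD(T) (trumpet)       1 + nu_s (1-q)            p_z (1-q)
SD(I) (isoflux)       1 + nu_s                  1
====================  =======================  ==============

Here ``nu_s`` is the size exponent of a wall-tethered chain, ``z_p`` the
dynamical exponent of tension propagation (``t ~ R_p^{z_p}``), ``gamma_p``
the subdiffusion exponent of the translocation coordinate during
propagation, ``q = (1-nu_b)/(1+nu_b)`` relates local monomer density to
blob velocity through the blob size exponent ``nu_b``, and ``p_z = z - 2``
(``z = 2 + 1/nu_b`` in Rouse dynamics) is the velocity-extension-force
exponent.  The regimes are demarcated by ``f1* ~ N^-1``,
``f2* ~ N^{-nu_s rho}`` and ``f3* ~ N^{-nu_s eta}`` with

    rho = (z_p (1-gamma_p) - 1 + q) / (p_z (1-q) - 1)
    eta = q / (p_z (1-q) - 1)

All scaling relations carry undetermined prefactors; curve outputs are
defined up to one global scale fixed by an anchor value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.integrate import quad

from .errors import AnalysisError, SingularParameterError

REGIMES = ("UB", "WD", "SD_T", "SD_I")

#: names of the five consistency inequalities the exponent set must satisfy
INEQUALITY_NAMES = ("nu_s*z_p*gamma_p < 2", "nu_s*rho < 1", "rho > eta",
                    "p_z*(1-q) > 1", "z_p*(1-gamma_p) > 1")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), applied only when reporting."""
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(exp, rounding=ROUND_HALF_UP))


@dataclass
class TheoryParameters:
    """The exponent set driving every closed-form prediction.

    Any subset may be given; :func:`derived_relations` closes the set using
    the inter-exponent relations.  ``rho`` and ``eta`` are derived boundary
    exponents.
    """

    nu_s: Optional[float] = None
    nu_b: Optional[float] = None
    gamma_p: Optional[float] = None
    z_p: Optional[float] = None
    z: Optional[float] = None
    p_z: Optional[float] = None
    q: Optional[float] = None
    rho: Optional[float] = None
    eta: Optional[float] = None

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise AnalysisError(f"theory parameter '{name}' is missing")

    def pz_one_minus_q(self) -> float:
        self.require("p_z", "q")
        return self.p_z * (1.0 - self.q)

    def zp_one_minus_gamma(self) -> float:
        self.require("z_p", "gamma_p")
        return self.z_p * (1.0 - self.gamma_p)


@dataclass
class RegimePrediction:
    """Exponents, boundaries and demarcation-line slopes for one parameter set."""

    alpha: Dict[str, float]
    delta: Dict[str, float]
    f_boundaries: Tuple[float, float, float]   # exponents of f1*, f2*, f3* in N
    N_boundaries: Tuple[float, float, float]   # exponents of N1*, N2*, N3* in f
    slopes_X: Tuple[float, float, float]
    slopes_Y: Tuple[float, float, float]


def regime_exponents(params: TheoryParameters, regime: str
                     ) -> Tuple[float, float]:
    """(alpha, delta) for one force regime."""
    if regime == "UB":
        params.require("nu_s")
        return 2.0 + params.nu_s * params.zp_one_minus_gamma(), 0.0
    if regime == "WD":
        params.require("nu_s")
        return 1.0 + params.nu_s * params.zp_one_minus_gamma(), 1.0
    if regime == "SD_T":
        params.require("nu_s", "q")
        return (1.0 + params.nu_s * (1.0 - params.q),
                params.pz_one_minus_q())
    if regime == "SD_I":
        params.require("nu_s")
        return 1.0 + params.nu_s, 1.0
    raise AnalysisError(f"unknown regime '{regime}'; expected one of {REGIMES}")


def boundary_exponents(params: TheoryParameters) -> Dict[str, float]:
    """Exponents of the three regime boundaries.

    ``f1* ~ N^-1`` (kBT/(N b), with b the bond length), ``f2* ~ N^{-nu_s rho}``
    and ``f3* ~ N^{-nu_s eta}``; the N-boundaries are the exact reciprocals,
    ``Nk* ~ f^{1/exponent(fk*)}``.
    """
    rho, eta = _rho_eta(params)
    params.require("nu_s")
    f1, f2, f3 = -1.0, -params.nu_s * rho, -params.nu_s * eta
    return {"f1": f1, "f2": f2, "f3": f3,
            "N1": 1.0 / f1, "N2": 1.0 / f2, "N3": 1.0 / f3}


def _rho_eta(params: TheoryParameters) -> Tuple[float, float]:
    if params.rho is not None and params.eta is not None:
        return params.rho, params.eta
    params.require("q")
    denom = params.pz_one_minus_q() - 1.0
    if denom == 0.0:
        raise SingularParameterError(
            "p_z (1-q) = 1 makes rho and eta singular")
    rho = (params.zp_one_minus_gamma() - 1.0 + params.q) / denom
    eta = params.q / denom
    return rho, eta


def boundary_slopes(params: TheoryParameters
                    ) -> Tuple[Tuple[float, float, float],
                               Tuple[float, float, float]]:
    """Slopes of the demarcation lines in the (f, tau) and (N, tau) planes.

    X1..X3 are the (negative) slopes of ``tau_Fk ~ f^{-Xk}``; Y1..Y3 the
    slopes of ``tau_Nk ~ N^{Yk}``.  Under the consistency inequalities the
    orderings X1 < X2 < X3 and Y1 > Y2 > Y3 hold.
    """
    params.require("nu_s", "q")
    rho, eta = _rho_eta(params)
    A = params.zp_one_minus_gamma()
    B = params.pz_one_minus_q()
    s = params.nu_s
    X1 = 2.0 + s * A
    X2 = (1.0 / s + 1.0 - params.q) / rho + B
    X3 = (1.0 / s + 1.0 - params.q) / eta + B
    Y1 = 2.0 + s * A
    Y2 = 1.0 + s * A + s * rho
    Y3 = 1.0 + s + s * eta
    return (X1, X2, X3), (Y1, Y2, Y3)


def regime_prediction(params: TheoryParameters) -> RegimePrediction:
    alpha = {}
    delta = {}
    for regime in REGIMES:
        a, d = regime_exponents(params, regime)
        alpha[regime] = a
        delta[regime] = d
    b = boundary_exponents(params)
    X, Y = boundary_slopes(params)
    return RegimePrediction(alpha=alpha, delta=delta,
                            f_boundaries=(b["f1"], b["f2"], b["f3"]),
                            N_boundaries=(b["N1"], b["N2"], b["N3"]),
                            slopes_X=X, slopes_Y=Y)


# ---------------------------------------------------------------------------
# inter-exponent relations
# ---------------------------------------------------------------------------

_RELATION_TOL = 0.05


def derived_relations(nu_s=None, nu_b=None, gamma_p=None, z_p=None,
                      z=None, p_z=None, q=None,
                      tol: float = _RELATION_TOL) -> Tuple[TheoryParameters,
                                                           Dict[str, float]]:
    """Close the exponent set using the scaling relations.

    Relations used: ``gamma_p = (1+nu_s)/(z_p nu_s)``,
    ``q = (1-nu_b)/(1+nu_b)``, ``p_z = z - 2`` and ``z = 2 + 1/nu_b``
    (Rouse dynamics).  Missing members are filled; when the inputs
    over-determine a relation the residual is reported instead of silently
    overwriting, and residuals beyond ``tol`` raise.

    Returns ``(params, residuals)``.
    """
    tp = TheoryParameters(nu_s=nu_s, nu_b=nu_b, gamma_p=gamma_p, z_p=z_p,
                          z=z, p_z=p_z, q=q)
    residuals: Dict[str, float] = {}
    filled: set = set()

    def _fill(name, value):
        current = getattr(tp, name)
        if current is None:
            setattr(tp, name, value)
            filled.add(name)
            return True
        residuals[name] = current - value
        return False

    changed = True
    while changed:
        changed = False
        # gamma_p = (1 + nu_s) / (z_p nu_s)
        if tp.nu_s is not None and tp.z_p is not None and tp.gamma_p is None:
            changed |= _fill("gamma_p", (1 + tp.nu_s) / (tp.z_p * tp.nu_s))
        if tp.nu_s is not None and tp.gamma_p is not None and tp.z_p is None:
            if tp.gamma_p * tp.nu_s == 0:
                raise SingularParameterError("gamma_p * nu_s = 0")
            changed |= _fill("z_p", (1 + tp.nu_s) / (tp.gamma_p * tp.nu_s))
        if tp.z_p is not None and tp.gamma_p is not None and tp.nu_s is None:
            denom = tp.z_p * tp.gamma_p - 1.0
            if denom > 0:
                changed |= _fill("nu_s", 1.0 / denom)
        # q = (1 - nu_b) / (1 + nu_b)
        if tp.nu_b is not None and tp.q is None:
            changed |= _fill("q", (1 - tp.nu_b) / (1 + tp.nu_b))
        if tp.q is not None and tp.nu_b is None:
            changed |= _fill("nu_b", (1 - tp.q) / (1 + tp.q))
        # z = 2 + 1/nu_b ; p_z = z - 2
        if tp.nu_b is not None and tp.z is None:
            changed |= _fill("z", 2.0 + 1.0 / tp.nu_b)
        if tp.z is not None and tp.p_z is None:
            changed |= _fill("p_z", tp.z - 2.0)
        if tp.p_z is not None and tp.z is None:
            changed |= _fill("z", tp.p_z + 2.0)

    # consistency residuals when every member of a relation was user-given
    def _all_given(*names):
        return all(getattr(tp, n) is not None and n not in filled
                   for n in names)

    if _all_given("nu_s", "z_p", "gamma_p"):
        residuals.setdefault(
            "gamma_p", tp.gamma_p - (1 + tp.nu_s) / (tp.z_p * tp.nu_s))
    if _all_given("nu_b", "q"):
        residuals.setdefault("q", tp.q - (1 - tp.nu_b) / (1 + tp.nu_b))

    bad = {k: v for k, v in residuals.items() if abs(v) > tol}
    if bad:
        raise AnalysisError(
            "inconsistent exponent closure; residuals beyond tolerance: "
            + ", ".join(f"{k}: {v:+.3f}" for k, v in bad.items()))
    try:
        tp.rho, tp.eta = _rho_eta(tp)
    except (AnalysisError, SingularParameterError):
        pass
    return tp, residuals


@dataclass
class InvertedExponents:
    """Exponents solved from the observed regime exponents.

    ``nu_s``, ``q`` and ``z_p`` are the unrounded solutions of

        nu_s = alpha_SD(I) - 1
        q    = 1 - (alpha_SD(T) - 1) / nu_s
        z_p  = (alpha_UB - 2) / (nu_s (1 - gamma_p))

    ``rho`` and ``eta`` follow the reporting convention of tabulated
    exponent chains: they are evaluated from the two-decimal reported
    values of ``z_p``, ``gamma_p``, ``q`` and ``delta_SD(T)``,

        rho = (z_p (1-gamma_p) - 1 + q) / (delta_SD(T) - 1)
        eta = q / (delta_SD(T) - 1)

    so that the derived column can be reproduced from the printed one.
    ``rho_raw``/``eta_raw`` carry the fully unrounded chain.
    """

    nu_s: float
    q: float
    z_p: float
    rho: float
    eta: float
    rho_raw: float
    eta_raw: float
    gamma_p: float
    delta_SDT: float

    def rounded(self) -> Dict[str, float]:
        """Two-decimal (half-up) report of the five derived exponents."""
        return {k: round_half_up(getattr(self, k))
                for k in ("nu_s", "q", "z_p", "rho", "eta")}

    def to_theory_params(self) -> TheoryParameters:
        """Unrounded TheoryParameters (p_z recovered from delta_SD(T))."""
        p_z = self.delta_SDT / (1.0 - self.q)
        return TheoryParameters(nu_s=self.nu_s, q=self.q, z_p=self.z_p,
                                gamma_p=self.gamma_p, p_z=p_z,
                                z=p_z + 2.0, nu_b=(1 - self.q) / (1 + self.q),
                                rho=self.rho_raw, eta=self.eta_raw)


def invert_observed(alpha_UB: float, alpha_SDT: float, alpha_SDI: float,
                    delta_SDT: float, gamma_p: float) -> InvertedExponents:
    """Solve (nu_s, q, z_p, rho, eta) from the observed regime exponents."""
    nu_s = alpha_SDI - 1.0
    if nu_s <= 0:
        raise AnalysisError("alpha_SD(I) must exceed 1 (nu_s > 0)")
    if gamma_p >= 1.0:
        raise SingularParameterError("gamma_p = 1 makes z_p singular")
    if delta_SDT == 1.0:
        raise SingularParameterError("delta_SD(T) = 1 makes rho, eta singular")
    q = 1.0 - (alpha_SDT - 1.0) / nu_s
    z_p = (alpha_UB - 2.0) / (nu_s * (1.0 - gamma_p))

    def _chain(zp_, q_):
        denom = delta_SDT - 1.0
        rho = (zp_ * (1.0 - gamma_p) - 1.0 + q_) / denom
        eta = q_ / denom
        return rho, eta

    rho_raw, eta_raw = _chain(z_p, q)
    rho, eta = _chain(round_half_up(z_p), round_half_up(q))
    return InvertedExponents(nu_s=nu_s, q=q, z_p=z_p, rho=rho, eta=eta,
                             rho_raw=rho_raw, eta_raw=eta_raw,
                             gamma_p=gamma_p, delta_SDT=delta_SDT)


def check_inequalities(params: TheoryParameters) -> Dict[str, Tuple[bool, float]]:
    """The five consistency predicates with their margins.

    A positive margin means the inequality holds by that amount.
    """
    params.require("nu_s", "z_p", "gamma_p", "q")
    rho, eta = _rho_eta(params)
    margins = {
        "nu_s*z_p*gamma_p < 2": 2.0 - params.nu_s * params.z_p * params.gamma_p,
        "nu_s*rho < 1": 1.0 - params.nu_s * rho,
        "rho > eta": rho - eta,
        "p_z*(1-q) > 1": params.pz_one_minus_q() - 1.0,
        "z_p*(1-gamma_p) > 1": params.zp_one_minus_gamma() - 1.0,
    }
    return {name: (m > 0, m) for name, m in margins.items()}


def pulled_chain_zp(nu_s0: float) -> float:
    """Tension-propagation exponent for a chain pulled by its head in free
    solution, where the front advances as ``m_p ~ t^(1/2)``: ``z_p = 2/nu_s0``."""
    if nu_s0 <= 0:
        raise SingularParameterError("nu_s0 must be positive")
    return 2.0 / nu_s0


# ---------------------------------------------------------------------------
# piecewise theory curves
# ---------------------------------------------------------------------------


def theory_curve(params: TheoryParameters, grid, mode: str,
                 N: Optional[float] = None, f: Optional[float] = None,
                 anchor: float = 1.0):
    """Piecewise power-law ``tau`` curve over a grid of f or N.

    ``mode='tau_vs_f'`` needs ``N``; ``mode='tau_vs_N'`` needs ``f``.
    Prefactors are fixed by continuity at each regime boundary; ``anchor``
    multiplies the whole curve (the theory fixes exponents only).

    Returns ``(grid, tau, regimes)`` with a regime label per grid point.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise AnalysisError("grid values must be positive")
    b = boundary_exponents(params)
    if mode == "tau_vs_f":
        if N is None:
            raise AnalysisError("tau_vs_f requires N")
        edges = [N ** b["f1"], N ** b["f2"], N ** b["f3"]]
        slopes = [0.0] + [-regime_exponents(params, r)[1]
                          for r in ("WD", "SD_T", "SD_I")]
        # at f = f1* the curve sits on the UB plateau tau = anchor * N^alpha_UB
        log_ref = math.log(anchor) + regime_exponents(params, "UB")[0] * math.log(N)
    elif mode == "tau_vs_N":
        if f is None:
            raise AnalysisError("tau_vs_N requires f")
        edges = [f ** b["N1"], f ** b["N2"], f ** b["N3"]]
        slopes = [regime_exponents(params, r)[0]
                  for r in ("UB", "WD", "SD_T", "SD_I")]
        log_ref = math.log(anchor) + slopes[0] * math.log(edges[0])
    else:
        raise AnalysisError("mode must be 'tau_vs_f' or 'tau_vs_N'")
    if not (edges[0] < edges[1] < edges[2]):
        raise SingularParameterError(
            "regime boundaries are not ordered for these exponents")

    labels = ("UB", "WD", "SD_T", "SD_I")
    # log-tau at the segment knots, built by continuity from edges[0]
    knot_level = [log_ref]
    for k in range(1, 3):
        knot_level.append(knot_level[-1] + slopes[k]
                          * (math.log(edges[k]) - math.log(edges[k - 1])))

    log_tau = np.empty_like(grid)
    regime_of = np.empty(grid.shape, dtype=object)
    log_edges = [math.log(e) for e in edges]
    for i, x in enumerate(grid):
        lx = math.log(x)
        k = sum(1 for le in log_edges if lx >= le)
        regime_of[i] = labels[k]
        ref = log_ref if k == 0 else knot_level[k - 1]
        base = log_edges[0] if k == 0 else log_edges[k - 1]
        log_tau[i] = ref + slopes[k] * (lx - base)
    return grid, np.exp(log_tau), regime_of


# ---------------------------------------------------------------------------
# numeric check of the propagation law
# ---------------------------------------------------------------------------


def solve_tension_ode(params: TheoryParameters, f: float, N: float,
                      variant: str = "trumpet",
                      include_subleading: bool = True,
                      r0: float = 1.0) -> float:
    """Propagation time ``tau_p`` by numeric integration of the front law.

    In the trumpet regime the tension front position obeys the reduced
    balance ``d/dt [ R^a - R^2 f^{-p_z q} ] = f^{p_z (1-q)}`` with
    ``a = 1/nu_s - q + 1``; the front reaches the chain end when
    ``R = N^{nu_s}``.  The isoflux variant integrates
    ``d/dt [ R^{1/nu_s + 1} - R^2 ] = f``.  ``include_subleading=False``
    drops the ``R^2`` term (negligible at large ``f`` in the trumpet case).

    Asymptotically ``tau_p ~ N^{1 + nu_s (1-q)} f^{-p_z (1-q)}`` (trumpet)
    and ``tau_p ~ N^{1 + nu_s} f^{-1}`` (isoflux).
    """
    if f <= 0:
        raise AnalysisError("f must be positive")
    params.require("nu_s")
    s = params.nu_s
    r_end = N ** s
    if r_end <= r0:
        raise AnalysisError("N too small for the chosen r0")
    if variant == "trumpet":
        params.require("q", "p_z")
        a = 1.0 / s - params.q + 1.0
        sub = f ** (-params.p_z * params.q)
        rate = f ** (params.p_z * (1.0 - params.q))

        def dF(r):
            g = a * r ** (a - 1.0)
            if include_subleading:
                g -= 2.0 * r * sub
            return g
    elif variant == "isoflux":
        a = 1.0 / s + 1.0
        rate = f

        def dF(r):
            g = a * r ** (a - 1.0)
            if include_subleading:
                g -= 2.0 * r
            return g
    else:
        raise AnalysisError("variant must be 'trumpet' or 'isoflux'")
    val, err = quad(dF, r0, r_end, limit=200)
    if not np.isfinite(val) or val <= 0:
        raise AnalysisError(
            "tension-front integration did not converge to a positive time; "
            f"value={val!r}, abserr={err!r}")
    return val / rate
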