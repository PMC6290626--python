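"""Estimators that turn translocation output into scaling exponents.

The estimators mirror how the exponents are extracted in practice:

* ``<tau>`` is averaged over completed runs only; failed runs are counted,
  never silently dropped.
* ``alpha`` and ``delta`` come from *pairs of adjacent points* on the
  log-log curves, reported at the geometric mean of the pair.
* ``nu_s0(m)`` and ``nu_b0(s)`` are the static size exponents,
  ``log(<R_m>/<R_1>)/log m`` and ``log(<R_ij>/<R_{s=1}>)/log s``.
* ``gamma`` is the log-log slope of the translocation-coordinate variance
  ``<Δn²>(t/<tau>)`` over a stated early-time window; the early-window
  estimate is the subdiffusion exponent ``gamma_p``.

A drift-diffusion trajectory generator (a time-rescaled biased integer
random walk with an absorbing boundary) provides synthetic ensembles with
planted drift and variance exponent, so every estimator can be validated
without molecular dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import AnalysisError
from .simulate import StaticChainSample, TranslocationEvent

#: default early-time window (in t/<tau>) for the gamma_p fit
GAMMA_WINDOW = (0.01, 0.1)


@dataclass
class ExponentEstimate:
    """One extracted scaling exponent with the abscissa it belongs to."""

    kind: str                 # alpha | delta | nu_s0 | nu_b0 | gamma
    value: float
    abscissa: float
    stderr: Optional[float] = None
    window: Optional[Tuple[float, float]] = None


def mean_tau(events: Sequence[TranslocationEvent]
             ) -> Tuple[float, Optional[float], int]:
    """Mean translocation time over completed runs.

    Returns ``(mean, stderr, n_completed)``; ``stderr`` is None for a
    single completed run.  Raises if no run completed.
    """
    taus = np.array([ev.tau for ev in events if ev.completed])
    if taus.size == 0:
        raise AnalysisError("no completed translocation events")
    mean = float(taus.mean())
    stderr = float(taus.std(ddof=1) / math.sqrt(taus.size)) if taus.size > 1 \
        else None
    return mean, stderr, int(taus.size)


def pairwise_exponent(x_pair: Tuple[float, float],
                      y_pair: Tuple[float, float],
                      sign: int = +1, kind: str = "alpha") -> ExponentEstimate:
    """Scaling exponent from one pair of adjacent log-log points.

    ``exponent = sign * log(y2/y1) / log(x2/x1)`` reported at the geometric
    mean ``sqrt(x1 x2)``.  ``delta`` uses ``sign=-1`` on (E, <tau>) pairs;
    ``alpha`` uses ``sign=+1`` on (N, <tau>) pairs.
    """
    x1, x2 = x_pair
    y1, y2 = y_pair
    if min(x1, x2, y1, y2) <= 0:
        raise AnalysisError("pairwise exponent requires positive inputs")
    if x1 == x2:
        raise AnalysisError("pair abscissae must differ")
    value = sign * math.log(y2 / y1) / math.log(x2 / x1)
    return ExponentEstimate(kind=kind, value=value,
                            abscissa=math.sqrt(x1 * x2))


def least_squares_exponent(points: Sequence[Tuple[float, float]],
                           kind: str = "alpha") -> ExponentEstimate:
    """Ordinary least-squares slope on (log x, log y)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise AnalysisError("need at least two points for a log-log fit")
    if np.any(pts <= 0):
        raise AnalysisError("log-log fit requires positive data")
    lx = np.log(pts[:, 0])
    ly = np.log(pts[:, 1])
    slope, _ = np.polyfit(lx, ly, 1)
    stderr = None
    if pts.shape[0] > 2:
        resid = ly - np.polyval(np.polyfit(lx, ly, 1), lx)
        sxx = np.sum((lx - lx.mean()) ** 2)
        stderr = float(np.sqrt(resid @ resid / (len(lx) - 2) / sxx))
    return ExponentEstimate(kind=kind, value=float(slope),
                            abscissa=float(np.exp(lx.mean())), stderr=stderr)


def exponent_map(x_values: Sequence[float], y_values: Sequence[float],
                 sign: int = +1, kind: str = "alpha") -> List[ExponentEstimate]:
    """Pairwise exponents along a curve, one per adjacent pair."""
    if len(x_values) != len(y_values):
        raise AnalysisError("x and y must have equal length")
    return [pairwise_exponent((x_values[k], x_values[k + 1]),
                              (y_values[k], y_values[k + 1]),
                              sign=sign, kind=kind)
            for k in range(len(x_values) - 1)]


# ---------------------------------------------------------------------------
# static size exponents
# ---------------------------------------------------------------------------


def nu_s0_profile(sample: StaticChainSample) -> List[ExponentEstimate]:
    """``nu_s0(m) = log(<R_m>/<R_1>) / log m`` for m >= 2."""
    if sample.mode != "tethered":
        raise AnalysisError("nu_s0 requires a tethered-chain sample")
    m = np.asarray(sample.abscissa)
    r = np.asarray(sample.distances)
    if 1 not in m:
        raise AnalysisError("sample must include m = 1 (<R_1> normaliser)")
    r1 = float(r[m == 1][0])
    out = []
    for mi, ri in zip(m, r):
        if mi < 2:
            continue  # log 1 = 0
        out.append(ExponentEstimate(kind="nu_s0",
                                    value=math.log(ri / r1) / math.log(mi),
                                    abscissa=float(mi)))
    return out


def nu_b0_profile(sample: StaticChainSample) -> List[ExponentEstimate]:
    """``nu_b0(s) = log(<R_ij>/<R_{s=1}>) / log s`` for separations s >= 2."""
    if sample.mode != "free":
        raise AnalysisError("nu_b0 requires a free-chain sample")
    s = np.asarray(sample.abscissa)
    r = np.asarray(sample.distances)
    if 1 not in s:
        raise AnalysisError("sample must include separation 1 (normaliser)")
    r1 = float(r[s == 1][0])
    out = []
    for si, ri in zip(s, r):
        if si < 2:
            continue
        out.append(ExponentEstimate(kind="nu_b0",
                                    value=math.log(ri / r1) / math.log(si),
                                    abscissa=float(si)))
    return out


# ---------------------------------------------------------------------------
# diffusion behaviour of the translocation coordinate
# ---------------------------------------------------------------------------


def _resample_locf(times: np.ndarray, values: np.ndarray,
                   t_query: np.ndarray) -> np.ndarray:
    """Step-function (last observation carried forward) resampling."""
    idx = np.searchsorted(times, t_query, side="right") - 1
    idx = np.clip(idx, 0, len(values) - 1)
    return values[idx]


def translocation_variance(events: Sequence[TranslocationEvent],
                           grid: np.ndarray) -> np.ndarray:
    """Ensemble variance ``<Δn²>`` of n(t) on a normalized-time grid.

    ``grid`` is in units of ``t/<tau>``; each run's step-function n(t) is
    resampled by last-observation-carried-forward before the across-run
    variance (population, ddof=0) is taken.  Once every run has completed,
    n is pinned at N and the variance is exactly zero.
    """
    completed = [ev for ev in events if ev.completed]
    if len(completed) < 2:
        raise AnalysisError("variance needs at least two completed events")
    tau_mean = float(np.mean([ev.tau for ev in completed]))
    grid = np.asarray(grid, dtype=float)
    t_query = grid * tau_mean
    samples = np.stack([_resample_locf(ev.times, ev.n_series, t_query)
                        for ev in completed])
    return samples.var(axis=0, ddof=0)


def fit_gamma(grid: np.ndarray, variance: np.ndarray,
              window: Tuple[float, float] = GAMMA_WINDOW) -> ExponentEstimate:
    """Log-log slope of the variance curve over a normalized-time window.

    With the default early-time window the estimate is the subdiffusion
    exponent ``gamma_p`` of the tension-propagation stage.
    """
    grid = np.asarray(grid, dtype=float)
    variance = np.asarray(variance, dtype=float)
    lo, hi = window
    mask = (grid >= lo) & (grid <= hi)
    if mask.sum() < 3:
        raise AnalysisError("fit window must contain at least 3 grid points")
    if np.any(variance[mask] <= 0):
        raise AnalysisError("variance must be positive inside the fit window")
    est = least_squares_exponent(np.column_stack([grid[mask], variance[mask]]),
                                 kind="gamma")
    est.window = (lo, hi)
    return est


# ---------------------------------------------------------------------------
# synthetic drift-diffusion trajectories
# ---------------------------------------------------------------------------


@dataclass
class DriftDiffusionSpec:
    """Planted dynamics for the synthetic trajectory generator.

    The translocation coordinate performs an integer random walk on
    ``[0, N]`` (reflecting at 0, absorbing at N) in an internal clock ``s``
    with drift ``drift`` and diffusion coefficient ``diffusion`` per unit
    ``s``; physical time is ``t = s**(1/gamma)``, so the ensemble variance
    grows as ``t**gamma`` before absorption.

    ``diffusion >= drift/2`` is required for a well-defined step scheme
    (``diffusion = 0`` with pure drift is the deterministic special case).
    """

    drift: float = 0.0
    diffusion: float = 0.5
    gamma: float = 1.0

    def __post_init__(self):
        if self.drift < 0 or self.diffusion < 0:
            raise AnalysisError("drift and diffusion must be >= 0")
        if self.gamma <= 0:
            raise AnalysisError("gamma must be positive")
        if self.diffusion == 0 and self.drift == 0:
            raise AnalysisError("either drift or diffusion must be positive")
        if self.diffusion > 0 and self.diffusion < self.drift / 2:
            raise AnalysisError("need diffusion >= drift/2 (or diffusion=0)")


def generate_synthetic_trajectories(n_runs: int, N: int,
                                    spec: DriftDiffusionSpec, seed: int,
                                    max_internal_steps: int = 2_000_000,
                                    record_stride: int = 1
                                    ) -> List[TranslocationEvent]:
    """Synthetic ensemble with planted drift and variance exponent.

    All ``n_runs`` walks are advanced simultaneously (vectorised over
    runs); each produces a TranslocationEvent whose ``tau`` is the
    absorption time at ``n = N`` mapped through the ``t = s**(1/gamma)``
    clock.
    """
    if n_runs < 1 or N < 1:
        raise AnalysisError("n_runs and N must be >= 1")
    rng = np.random.default_rng(seed)
    v, D = spec.drift, spec.diffusion
    if D == 0.0:
        ds = 1.0 / v
        p_up, p_dn = 1.0, 0.0
    else:
        # per-step probabilities: mean v*ds, variance ~ 2D*ds
        ds = 0.25 / (D + v / 2.0)
        p_up = ds * (D + v / 2.0)
        p_dn = ds * (D - v / 2.0)

    n = np.zeros(n_runs, dtype=np.int64)
    alive = np.ones(n_runs, dtype=bool)
    s_abs = np.full(n_runs, np.nan)
    rec_t: List[List[float]] = [[0.0] for _ in range(n_runs)]
    rec_n: List[List[int]] = [[0] for _ in range(n_runs)]

    step = 0
    while alive.any() and step < max_internal_steps:
        step += 1
        u = rng.random(n_runs)
        move = np.zeros(n_runs, dtype=np.int64)
        move[u < p_up] = 1
        move[(u >= p_up) & (u < p_up + p_dn)] = -1
        n = np.where(alive, np.maximum(0, n + move), n)  # reflect at 0
        newly = alive & (n >= N)
        s_abs[newly] = step * ds
        alive &= ~newly
        if step % record_stride == 0 or newly.any():
            t_now = (step * ds) ** (1.0 / spec.gamma)
            for i in np.flatnonzero(alive | newly):
                rec_t[i].append(t_now)
                rec_n[i].append(int(min(n[i], N)))

    events = []
    for i in range(n_runs):
        completed = not alive[i]
        tau = float(s_abs[i] ** (1.0 / spec.gamma)) if completed else float("nan")
        events.append(TranslocationEvent(
            tau=tau, times=np.asarray(rec_t[i]),
            n_series=np.asarray(rec_n[i], dtype=float),
            cis_series=np.asarray([N - v_ for v_ in rec_n[i]], dtype=float),
            seed=seed + i,
            status="completed" if completed else "max_time_reached",
            N=N))
    return events


def expected_absorption_steps(N: int, spec: DriftDiffusionSpec) -> float:
    """Exact mean absorption time (internal clock) of the generator's walk.

    Independent oracle: solves the first-step linear system for the
    discrete chain actually used by the generator (reflecting 0,
    absorbing N), for validating the simulated mean tau.
    """
    v, D = spec.drift, spec.diffusion
    if D == 0.0:
        return N / v
    ds = 0.25 / (D + v / 2.0)
    p_up = ds * (D + v / 2.0)
    p_dn = ds * (D - v / 2.0)
    # T(k) = 1 + p_up T(k+1) + p_dn T(k-1) + (1-p_up-p_dn) T(k), T(N)=0
    A = np.zeros((N, N))
    b = np.ones(N)
    for k in range(N):
        A[k, k] = p_up + p_dn
        if k + 1 < N:
            A[k, k + 1] = -p_up
        if k - 1 >= 0:
            A[k, k - 1] = -p_dn
        else:
            A[k, k] -= p_dn  # reflection at 0
    steps = np.linalg.solve(A, b)
    return float(steps[0] * ds)
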