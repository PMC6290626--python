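"""Simulation-unit <-> experimental-unit conversion for nanopore records.

The coarse-grained bead maps onto double-stranded DNA with one bead per
~0.7 bp, a time unit of ~2.13 ps and a driving-field unit of
~100 mV/nm.  With those three constants a published translocation
experiment (contour length in bp, duration in seconds, transmembrane
field in mV/nm) can be placed on the simulation's (N, tau, E) scaling
plot and vice versa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .errors import AnalysisError


@dataclass
class UnitSystem:
    """Physical magnitude of the simulation units."""

    sigma_bp: float = 0.7          # base pairs per sigma
    tu_ps: float = 2.13           # picoseconds per time unit
    Eu_mV_per_nm: float = 100.0   # mV/nm per field unit

    def __post_init__(self):
        if min(self.sigma_bp, self.tu_ps, self.Eu_mV_per_nm) <= 0:
            raise AnalysisError("unit constants must be positive")


@dataclass
class ExperimentRecord:
    """One published nanopore translocation measurement."""

    label: str
    contour_bp: float
    tau_seconds: float
    field_mV_per_nm: float
    salt: str = "monovalent"       # monovalent | divalent

    def __post_init__(self):
        if min(self.contour_bp, self.tau_seconds, self.field_mV_per_nm) <= 0:
            raise AnalysisError("experiment record magnitudes must be positive")
        if self.salt not in ("monovalent", "divalent"):
            raise AnalysisError("salt must be 'monovalent' or 'divalent'")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half-up."""
    if x == 0:
        return 0.0
    from decimal import ROUND_HALF_UP, Decimal
    d = Decimal(repr(float(x)))
    shift = sig - 1 - int(math.floor(math.log10(abs(x))))
    exp = Decimal(1).scaleb(-shift)
    return float(d.quantize(exp, rounding=ROUND_HALF_UP))


def to_simulation_units(rec: ExperimentRecord,
                        units: Optional[UnitSystem] = None
                        ) -> Tuple[int, float, float]:
    """(N, tau_sim, E_sim) for an experimental record.

    ``N = round(bp / sigma_bp)``; ``tau_sim = tau / tu``;
    ``E_sim = field / Eu``.
    """
    if units is None:
        units = UnitSystem()
    N = int(round(rec.contour_bp / units.sigma_bp))
    tau_sim = rec.tau_seconds / (units.tu_ps * 1.0e-12)
    E_sim = rec.field_mV_per_nm / units.Eu_mV_per_nm
    return N, tau_sim, E_sim


def from_simulation_units(N: float, tau_sim: float, E_sim: float,
                          units: Optional[UnitSystem] = None,
                          label: str = "", salt: str = "monovalent"
                          ) -> ExperimentRecord:
    """Inverse map (exact up to the integer rounding of N)."""
    if units is None:
        units = UnitSystem()
    return ExperimentRecord(
        label=label,
        contour_bp=N * units.sigma_bp,
        tau_seconds=tau_sim * units.tu_ps * 1.0e-12,
        field_mV_per_nm=E_sim * units.Eu_mV_per_nm,
        salt=salt)


def comparison_table(records: Sequence[ExperimentRecord],
                     simulated: Sequence[Tuple[int, float, float]],
                     units: Optional[UnitSystem] = None,
                     sim_E: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Tidy (source, salt, N, tau, E) table in simulation units.

    ``simulated`` holds ``(Z, N, mean_tau)`` triples; ``sim_E`` optionally
    supplies the matching field strengths.  Suitable for a log-log
    tau-versus-N overlay of experiments and simulations.
    """
    if len(records) == 0:
        raise AnalysisError("no experiment records supplied")
    if len(simulated) == 0:
        raise AnalysisError("no simulated points supplied")
    rows = []
    for rec in records:
        N, tau, E = to_simulation_units(rec, units)
        rows.append(dict(source="experiment", label=rec.label, salt=rec.salt,
                         N=N, tau=tau, E=E))
    for k, (Z, N, tau) in enumerate(simulated):
        rows.append(dict(source="simulation", label=f"Z={Z}",
                         salt="monovalent" if Z == 1 else "divalent",
                         N=int(N), tau=float(tau),
                         E=float(sim_E[k]) if sim_E is not None else float("nan")))
    return pd.DataFrame(rows)
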