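"""Configuration and file round-trips: TOML config, CSV/HDF5/XYZ output.

All numeric output is in simulation units (sigma, tu, kBT/(e sigma))
unless a :class:`~poretrans.units.UnitSystem` is attached by the caller;
file headers carry the unit convention.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import SPECIES_NAMES, ParticleSystem, SimulationParameters
from .simulate import TranslocationEvent

_ANALYSIS_KEYS = {"gamma_window", "variance_grid_points", "sample_interval"}
_SWEEP_KEYS = {"E", "Nm", "n_runs", "seed0", "max_time"}
_SECTION_NAMES = {"analysis", "sweep", "theory"}


def load_config(path) -> Tuple[SimulationParameters, Dict]:
    """Read a TOML config into (SimulationParameters, extra sections).

    Top-level keys configure the simulation and must match
    SimulationParameters fields; ``Z`` has no default and must be stated.
    Optional ``[analysis]``, ``[sweep]`` and ``[theory]`` tables are
    returned verbatim (with key validation for the first two).  Unknown
    keys raise :class:`ConfigError` naming the key.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sections = {}
    sim_kwargs = {}
    valid = set(SimulationParameters.field_names())
    for key, value in raw.items():
        if key in _SECTION_NAMES:
            sections[key] = value
            continue
        if key not in valid:
            raise ConfigError(f"unknown configuration key '{key}'", key=key)
        sim_kwargs[key] = tuple(value) if key == "box" else value
    if "Z" not in sim_kwargs:
        raise ConfigError(
            "the salt valence Z must be stated explicitly (Z = 1 or Z = 2); "
            "all other keys default to the standard parameter set", key="Z")
    for key in sections.get("analysis", {}):
        if key not in _ANALYSIS_KEYS:
            raise ConfigError(f"unknown [analysis] key '{key}'", key=key)
    for key in sections.get("sweep", {}):
        if key not in _SWEEP_KEYS:
            raise ConfigError(f"unknown [sweep] key '{key}'", key=key)
    params = SimulationParameters(**sim_kwargs)
    return params, sections


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------


def events_to_frame(events: Sequence[TranslocationEvent],
                    params: SimulationParameters) -> pd.DataFrame:
    """One row per run: seed, tau, status, N, Z, E (simulation units)."""
    return pd.DataFrame([
        dict(seed=ev.seed, tau=ev.tau, status=ev.status, N=ev.N,
             Z=params.Z, E=params.E)
        for ev in events])


def write_events_csv(events, params, path) -> None:
    events_to_frame(events, params).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_n_series_csv(event: TranslocationEvent, path) -> None:
    """Two-column (t, n) series for one run; t in tu."""
    pd.DataFrame({"t": event.times, "n": event.n_series}).to_csv(path,
                                                                 index=False)


def read_n_series_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_batch_hdf5(events: Sequence[TranslocationEvent], path,
                     params: SimulationParameters) -> None:
    """All runs of a batch in one HDF5 container (one group per run)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["Z"] = params.Z
        fh.attrs["E"] = params.E
        fh.attrs["Nm"] = params.Nm
        fh.attrs["units"] = "sigma, tu, kBT/(e sigma)"
        for k, ev in enumerate(events):
            g = fh.create_group(f"run{k:04d}")
            g.attrs["seed"] = ev.seed
            g.attrs["tau"] = ev.tau
            g.attrs["status"] = ev.status
            g.attrs["N"] = ev.N
            g.create_dataset("t", data=ev.times)
            g.create_dataset("n", data=ev.n_series)
            g.create_dataset("cis", data=ev.cis_series)


def read_batch_hdf5(path) -> List[TranslocationEvent]:
    events = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh.keys()):
            g = fh[name]
            events.append(TranslocationEvent(
                tau=float(g.attrs["tau"]), times=g["t"][...],
                n_series=g["n"][...], cis_series=g["cis"][...],
                seed=int(g.attrs["seed"]), status=str(g.attrs["status"]),
                N=int(g.attrs["N"])))
    return events


# ---------------------------------------------------------------------------
# extended-XYZ trajectory frames
# ---------------------------------------------------------------------------


def write_xyz_frame(fh, system: ParticleSystem, time: float = 0.0) -> None:
    """Append one extended-XYZ frame (species, position, charge)."""
    L = system.box
    fh.write(f"{system.n_particles}\n")
    fh.write(
        f'Lattice="{L[0]} 0 0 0 {L[1]} 0 0 0 {L[2]}" '
        f'Properties=species:S:1:pos:R:3:charge:R:1 Time={time}\n')
    for sp, p, q in zip(system.species, system.positions, system.charges):
        name = SPECIES_NAMES[int(sp)]
        fh.write(f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {q:.1f}\n")


def read_xyz_frames(path):
    """Parse frames written by :func:`write_xyz_frame`.

    Returns a list of (species names, positions, charges, comment).
    """
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        comment = lines[i + 1]
        names, pos, q = [], [], []
        for line in lines[i + 2:i + 2 + n]:
            parts = line.split()
            names.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
            q.append(float(parts[4]))
        frames.append((names, np.asarray(pos), np.asarray(q), comment))
        i += 2 + n
    return frames
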