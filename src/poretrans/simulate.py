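"""Langevin dynamics driver: system builders, integrator and run protocols.

A translocation run follows the protocol of the driven-translocation
experiment: the chain is threaded through the pore with the head monomer
held just beyond the exit, the system is relaxed under that constraint with
the field off, then the constraint is released and the pore field switched
on simultaneously.  The translocation time ``tau`` is the last time any
monomer occupies the cis compartment, evaluated once the whole chain sits
on the trans side with a hysteresis margin (centre of mass at least one
radius of gyration beyond the wall) so that a return is no longer possible
in practice.  The translocation coordinate ``n(t)`` counts trans-side
monomers beyond the five that primed the pore, so a completed run ends at
``n = Nm - 5``.

Two auxiliary static systems support the size-exponent estimators: a chain
tethered to the wall by a fixed anchor (mean monomer-to-anchor distance
``<R_m>``), and a free chain in salt solution (mean pair distance
``<R_ij>`` per bond separation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import _kernels
from .electrostatics import ewald_energy_forces
from .errors import ConfigError, InstabilityError, PackingError
from .model import (ANCHOR, CHAIN_COUNTERION, MONOMER, SALT_ANION,
                    SALT_CATION, WALL_BEAD, ParticleSystem,
                    SimulationParameters, wall_surface_distance)

MAX_STEP_DISPLACEMENT = 0.5  # sigma; larger means the timestep is unstable

# insertion clearances (sigma)
_PAIR_CLEARANCE = 0.95
_WALL_CLEARANCE = 1.55


@dataclass
class TranslocationEvent:
    """Outcome of one translocation run."""

    tau: float
    times: np.ndarray
    n_series: np.ndarray
    cis_series: np.ndarray
    seed: int
    status: str              # "completed" | "max_time_reached"
    N: int

    @property
    def completed(self) -> bool:
        return self.status == "completed"


@dataclass
class StaticChainSample:
    """Equilibrium chain-size statistics from a static (non-driven) run."""

    mode: str                # "tethered" | "free"
    abscissa: np.ndarray     # monomer index m, or bond separation |i-j|
    distances: np.ndarray    # <R_m> or <R_ij>
    n_samples: int


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


def _nb_kind(system: ParticleSystem) -> np.ndarray:
    kind = np.zeros(system.n_particles, dtype=np.int8)
    kind[system.species == WALL_BEAD] = 1
    kind[system.species == ANCHOR] = 2
    return kind


def _force_args(params: SimulationParameters, field_on: bool,
                head_idx: int, wall_on: bool):
    mode = params.electrostatics_mode
    rc = params.resolved_coulomb_cutoff() if mode == "dsf" else 0.0
    alpha = params.resolved_dsf_alpha() if mode == "dsf" else 0.0
    return (params.eps_pp, params.sigma_pp, params.eps_pw, params.sigma_pw,
            params.lambda_B, alpha, rc,
            params.k_bond, params.b0,
            params.half_wall, params.pore_radius, params.E,
            1 if field_on else 0,
            1 if wall_on else 0,
            head_idx, params.barrier_eps, params.barrier_sigma,
            1 if params.excluded_volume else 0)


def forces_and_energy(system: ParticleSystem, params: SimulationParameters,
                      field_on: bool = True, barrier: bool = True):
    """Total forces and potential energy under the configured solver."""
    head_idx = system.head_index if barrier else -1
    wall_on = params.wall and not params.explicit_wall
    F = np.zeros_like(system.positions)
    args = _force_args(params, field_on, head_idx, wall_on)
    U = _kernels.compute_forces(system.positions, system.charges,
                                _nb_kind(system), system.bonds, system.box,
                                *args, F)
    if params.electrostatics_mode == "ewald":
        charged = np.flatnonzero(system.charges != 0.0)
        if charged.size:
            e, f = ewald_energy_forces(system.positions[charged],
                                       system.charges[charged],
                                       system.box, params.lambda_B)
            U += e
            F[charged] += f
    return F, U


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _advance(system: ParticleSystem, params: SimulationParameters,
             rng: np.random.Generator, n_steps: int,
             field_on: bool, barrier: bool = True,
             chunk: int = 200) -> None:
    """Advance the system by ``n_steps`` Langevin steps in place."""
    if params.electrostatics_mode == "ewald":
        raise ConfigError(
            "dynamics requires electrostatics_mode 'dsf' or 'none'; "
            "'ewald' is the reference solver for energy/force evaluation",
            key="electrostatics_mode")
    head_idx = system.head_index if barrier else -1
    wall_on = params.wall and not params.explicit_wall
    args = _force_args(params, field_on, head_idx, wall_on)
    nb_kind = _nb_kind(system)
    F = np.zeros_like(system.positions)
    _kernels.compute_forces(system.positions, system.charges, nb_kind,
                            system.bonds, system.box, *args, F)
    gamma = params.gamma
    std = math.sqrt(2.0 * gamma / params.dt)
    n = system.n_particles
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        noise = (rng.normal(0.0, std, size=(m, n, 3))
                 if gamma > 0 else np.zeros((m, n, 3)))
        _, maxdisp = _kernels.integrate_chunk(
            system.positions, system.velocities, F, system.mobile,
            system.charges, nb_kind, system.bonds, system.box, noise,
            params.dt, gamma, *args)
        if maxdisp > MAX_STEP_DISPLACEMENT:
            raise InstabilityError(
                f"per-step displacement {maxdisp:.3f} sigma exceeds "
                f"{MAX_STEP_DISPLACEMENT}; reduce dt (currently {params.dt})")
        done += m


def langevin_step(system: ParticleSystem, params: SimulationParameters,
                  rng: np.random.Generator, field_on: bool = True,
                  barrier: bool = True) -> ParticleSystem:
    """One velocity-Verlet Langevin update (in place; returns the system)."""
    _advance(system, params, rng, 1, field_on=field_on, barrier=barrier,
             chunk=1)
    return system


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _maxwell_velocities(rng, n, mobile):
    v = rng.normal(0.0, 1.0, size=(n, 3))
    v[~mobile] = 0.0
    return v


def _insert_ions(rng, existing, box, params, counts, clearance_pairs,
                 wall_active, max_tries=2000):
    """Uniform random insertion of ions avoiding overlaps and the wall."""
    placed = []
    half = box / 2.0
    for _ in range(counts):
        for attempt in range(max_tries):
            p = rng.uniform(-half, half)
            if wall_active and wall_surface_distance(p, params) < _WALL_CLEARANCE:
                continue
            pool = existing + placed
            ok = True
            for qpos in pool:
                d = p - qpos
                d -= box * np.round(d / box)
                if d @ d < clearance_pairs ** 2:
                    ok = False
                    break
            if ok:
                placed.append(p)
                break
        else:
            raise PackingError(
                f"could not insert ion after {max_tries} attempts; "
                "box too crowded")
    return placed


def _grow_chain(rng, start, bias, n_grow, existing, box, params,
                wall_active, max_tries=80, restarts=40):
    """Grow a bead-spring chain by biased random placement with retries."""
    for _ in range(restarts):
        chain = [start]
        failed = False
        for _k in range(n_grow):
            prev = chain[-1]
            for attempt in range(max_tries):
                u = rng.normal(size=3)
                direction = bias + 0.9 * u / np.linalg.norm(u)
                direction /= np.linalg.norm(direction)
                p = prev + params.b0 * direction
                # keep inside the box x-range; y,z wrap periodically
                if abs(p[0]) > box[0] / 2.0 - 1.0:
                    continue
                if wall_active and wall_surface_distance(p, params) < _WALL_CLEARANCE:
                    continue
                ok = True
                for qpos in existing + chain[:-1]:
                    d = p - qpos
                    d -= box * np.round(d / box)
                    if d @ d < 0.81:  # 0.9 sigma self-clearance
                        ok = False
                        break
                if ok:
                    chain.append(p)
                    break
            else:
                failed = True
                break
        if not failed:
            return chain[1:]
    raise PackingError("chain growth failed; box too crowded for the chain")


def wall_bead_positions(params: SimulationParameters) -> np.ndarray:
    """Cubic lattice (spacing 1 sigma) filling the slab, minus the pore."""
    hw = params.half_wall
    Lx, Ly, Lz = params.box
    xs = np.arange(-hw + 0.5, hw, 1.0)
    ys = np.arange(-Ly / 2 + 0.5, Ly / 2, 1.0)
    zs = np.arange(-Lz / 2 + 0.5, Lz / 2, 1.0)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    keep = np.hypot(pts[:, 1], pts[:, 2]) >= params.pore_radius
    return pts[keep]


def _salt_counts(params: SimulationParameters):
    """(cation count, cation valence, anion count) for the added (Z:1)-salt."""
    return params.n_salt, params.Z, params.n_salt * params.Z


def _assemble(params, monomer_pos, rng, extra_species=(), extra_pos=(),
              wall_active=True, head_index=0,
              anchor_bond=False):
    """Common assembly: chain + counterions + salt (+ wall/anchor beads)."""
    box = np.asarray(params.box, dtype=float)
    Nm = len(monomer_pos)
    pos_list = list(monomer_pos)
    species = [MONOMER] * Nm
    charges = [0.0 if params.neutral_chain else -1.0] * Nm

    existing = list(pos_list)
    if not params.neutral_chain:
        ci = _insert_ions(rng, existing, box, params, Nm, _PAIR_CLEARANCE,
                          wall_active)
        existing += ci
        pos_list += ci
        species += [CHAIN_COUNTERION] * Nm
        charges += [1.0] * Nm
    n_cat, z_cat, n_an = _salt_counts(params)
    if params.n_salt > 0 and not params.neutral_chain:
        cat = _insert_ions(rng, existing, box, params, n_cat, _PAIR_CLEARANCE,
                           wall_active)
        existing += cat
        pos_list += cat
        species += [SALT_CATION] * n_cat
        charges += [float(z_cat)] * n_cat
        an = _insert_ions(rng, existing, box, params, n_an, _PAIR_CLEARANCE,
                          wall_active)
        existing += an
        pos_list += an
        species += [SALT_ANION] * n_an
        charges += [-1.0] * n_an

    for sp, p in zip(extra_species, extra_pos):
        pos_list.append(np.asarray(p, dtype=float))
        species.append(sp)
        charges.append(0.0)

    if params.explicit_wall and wall_active:
        for p in wall_bead_positions(params):
            pos_list.append(p)
            species.append(WALL_BEAD)
            charges.append(0.0)

    positions = np.asarray(pos_list, dtype=float)
    species = np.asarray(species, dtype=np.int8)
    charges = np.asarray(charges, dtype=float)
    mobile = ~np.isin(species, (WALL_BEAD, ANCHOR))

    bonds = [(i, i + 1) for i in range(Nm - 1)]
    if anchor_bond:
        anchor_idx = int(np.flatnonzero(species == ANCHOR)[0])
        bonds.append((anchor_idx, 0))
    bonds = np.asarray(bonds, dtype=np.int64)

    velocities = _maxwell_velocities(rng, len(positions), mobile)
    return ParticleSystem(positions=positions, velocities=velocities,
                          charges=charges, species=species, bonds=bonds,
                          box=box, mobile=mobile, head_index=head_index)


def build_initial_state(params: SimulationParameters,
                        rng: Optional[np.random.Generator] = None,
                        relax: bool = True) -> ParticleSystem:
    """Thread the chain through the pore and fill the box with ions.

    The head monomer (index 0) sits at barrier contact just beyond the pore
    exit; monomers 2-5 run back through the channel and the chain body is
    grown into the cis compartment.  With ``relax=True`` the system is then
    equilibrated under the head constraint (field off) for
    ``params.resolved_relax_time()``.
    """
    own_rng = rng is None
    if own_rng:
        rng = np.random.default_rng(params.seed)
    hw = params.half_wall
    spacing = 1.02 * params.b0
    head = np.array([hw + 1.0, 0.0, 0.0])
    pore_chain = [head - np.array([k * spacing, 0.0, 0.0]) for k in range(5)]
    # continue straight down the axis until clear of the pore mouth
    tail_start = pore_chain[-1]
    straight = []
    p = tail_start.copy()
    while p[0] - spacing > -params.box[0] / 2 + 2.0 and p[0] >= -hw - 1.2:
        p = p - np.array([spacing, 0.0, 0.0])
        straight.append(p.copy())
    seed_chain = pore_chain + straight
    n_grow = params.Nm - len(seed_chain)
    if n_grow < 0:
        seed_chain = seed_chain[:params.Nm]
        n_grow = 0
    body = _grow_chain(rng, seed_chain[-1], np.array([-0.9, 0.0, 0.0]),
                       n_grow, seed_chain[:-1], np.asarray(params.box),
                       params, wall_active=params.wall)
    monomers = seed_chain + body
    system = _assemble(params, monomers, rng, wall_active=params.wall,
                       head_index=0)
    if relax:
        equilibrate(system, params, params.resolved_relax_time(), rng,
                    hold_head=True)
    return system


def equilibrate(system: ParticleSystem, params: SimulationParameters,
                duration: float, rng: np.random.Generator,
                hold_head: bool = False) -> None:
    """Relax the system (field off) for ``duration`` tu, in place."""
    if duration <= 0:
        return
    if hold_head:
        was_mobile = system.mobile[system.head_index]
        system.mobile[system.head_index] = False
        system.velocities[system.head_index] = 0.0
    n_steps = max(1, int(round(duration / params.dt)))
    _advance(system, params, rng, n_steps, field_on=False)
    if hold_head:
        system.mobile[system.head_index] = was_mobile


# ---------------------------------------------------------------------------
# translocation protocol
# ---------------------------------------------------------------------------


def _radius_of_gyration(chain_xyz: np.ndarray) -> float:
    com = chain_xyz.mean(axis=0)
    return float(np.sqrt(((chain_xyz - com) ** 2).sum(axis=1).mean()))


def run_translocation(params: SimulationParameters,
                      max_time: Optional[float] = None,
                      sample_interval: float = 0.25,
                      rng: Optional[np.random.Generator] = None,
                      system: Optional[ParticleSystem] = None
                      ) -> TranslocationEvent:
    """One full translocation run: build, relax, release, integrate.

    Sampling happens every ``sample_interval`` tu.  The run ends when every
    monomer is on the trans side and the chain centre of mass is at least
    one radius of gyration beyond the wall (so a cis return can no longer
    occur), or when ``max_time`` is exceeded.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if system is None:
        system = build_initial_state(params, rng=rng, relax=True)
    if max_time is None:
        max_time = params.resolved_max_time()
    hw = params.half_wall
    stride = max(1, int(round(sample_interval / params.dt)))
    dt_sample = stride * params.dt

    times = [0.0]
    cis0, _, _ = system.region_counts(hw)
    cis_series = [cis0]
    n_series = [_n_coordinate(system, hw)]
    t = 0.0
    t_last_cis = 0.0 if cis0 > 0 else np.nan
    status = "max_time_reached"
    while t < max_time:
        _advance(system, params, rng, stride, field_on=True, chunk=stride)
        t += dt_sample
        cis, pore, trans = system.region_counts(hw)
        times.append(t)
        cis_series.append(cis)
        n_series.append(_n_coordinate(system, hw))
        if cis > 0:
            t_last_cis = t
        elif pore == 0:
            chain = system.unwrapped_chain()
            rg = _radius_of_gyration(chain)
            if chain[:, 0].mean() > hw + rg:
                status = "completed"
                break
    tau = t_last_cis if status == "completed" else float("nan")
    return TranslocationEvent(tau=tau, times=np.asarray(times),
                              n_series=np.asarray(n_series, dtype=float),
                              cis_series=np.asarray(cis_series, dtype=float),
                              seed=params.seed, status=status, N=params.N)


def _n_coordinate(system: ParticleSystem, hw: float) -> int:
    """Translocation coordinate: trans-side monomers beyond the five primers."""
    _, _, trans = system.region_counts(hw)
    return max(0, trans - 5)


def run_batch(params: SimulationParameters, n_runs: int, seed0: int,
              max_time: Optional[float] = None,
              sample_interval: float = 0.25) -> List[TranslocationEvent]:
    """Independent runs with seeds ``seed0 .. seed0 + n_runs - 1``."""
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1", key="n_runs")
    events = []
    for k in range(n_runs):
        p = params.replace(seed=seed0 + k)
        events.append(run_translocation(p, max_time=max_time,
                                        sample_interval=sample_interval))
    return events


# ---------------------------------------------------------------------------
# static samplers
# ---------------------------------------------------------------------------


def build_tethered_state(params: SimulationParameters,
                         rng: np.random.Generator) -> ParticleSystem:
    """Chain anchored to the wall face on the trans side; no pore threading."""
    hw = params.half_wall
    anchor = np.array([hw + 1.3, 0.0, 0.0]) if params.wall else np.zeros(3)
    first = anchor + np.array([params.b0, 0.0, 0.0])
    body = _grow_chain(rng, first, np.array([0.9, 0.0, 0.0]),
                       params.Nm - 1, [anchor], np.asarray(params.box),
                       params, wall_active=params.wall)
    monomers = [first] + body
    return _assemble(params, monomers, rng, extra_species=(ANCHOR,),
                     extra_pos=(anchor,), wall_active=params.wall,
                     head_index=-1, anchor_bond=True)


def build_free_state(params: SimulationParameters,
                     rng: np.random.Generator) -> ParticleSystem:
    """Free chain in salt solution (no wall, no field)."""
    p = params.replace(wall=False)
    first = np.zeros(3)
    body = _grow_chain(rng, first, np.zeros(3), p.Nm - 1, [],
                       np.asarray(p.box), p, wall_active=False)
    return _assemble(p, [first] + body, rng, wall_active=False, head_index=-1)


def _sample_static(system, params, rng, n_samples, equil_time,
                   sample_interval, reducer):
    equilibrate(system, params, equil_time, rng)
    stride = max(1, int(round(sample_interval / params.dt)))
    acc = None
    for _ in range(n_samples):
        _advance(system, params, rng, stride, field_on=False, barrier=False,
                 chunk=stride)
        val = reducer(system)
        acc = val if acc is None else acc + val
    return acc / n_samples


def sample_tethered_chain(params: SimulationParameters, n_samples: int,
                          equil_time: Optional[float] = None,
                          sample_interval: float = 2.0,
                          rng: Optional[np.random.Generator] = None
                          ) -> StaticChainSample:
    """Equilibrium ``<R_m>``: mean distance of monomer m to the tether point."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if equil_time is None:
        equil_time = 3.0 * params.Nm
    system = build_tethered_state(params, rng)
    anchor_idx = int(np.flatnonzero(system.species == ANCHOR)[0])
    anchor = system.positions[anchor_idx].copy()

    def reducer(sys_):
        chain = sys_.unwrapped_chain()
        # re-reference the unwrapped chain to the anchor through monomer 1
        d1 = sys_.positions[sys_.monomer_indices()[0]] - anchor
        d1 -= sys_.box * np.round(d1 / sys_.box)
        shifted = chain - chain[0] + d1
        return np.sqrt((shifted ** 2).sum(axis=1))

    mean_r = _sample_static(system, params, rng, n_samples, equil_time,
                            sample_interval, reducer)
    return StaticChainSample(mode="tethered",
                             abscissa=np.arange(1, params.Nm + 1),
                             distances=mean_r, n_samples=n_samples)


def sample_free_chain(params: SimulationParameters, n_samples: int,
                      equil_time: Optional[float] = None,
                      sample_interval: float = 2.0,
                      rng: Optional[np.random.Generator] = None
                      ) -> StaticChainSample:
    """Equilibrium ``<R_ij>`` versus bond separation ``s = |i - j|``.

    Averages over every monomer pair at fixed separation and over
    ``n_samples`` snapshots.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if equil_time is None:
        equil_time = 3.0 * params.Nm
    p = params.replace(wall=False)
    system = build_free_state(p, rng)
    Nm = p.Nm

    def reducer(sys_):
        chain = sys_.unwrapped_chain()
        out = np.empty(Nm - 1)
        for s in range(1, Nm):
            d = chain[s:] - chain[:-s]
            out[s - 1] = np.sqrt((d ** 2).sum(axis=1)).mean()
        return out

    mean_r = _sample_static(system, p, rng, n_samples, equil_time,
                            sample_interval, reducer)
    return StaticChainSample(mode="free", abscissa=np.arange(1, Nm),
                             distances=mean_r, n_samples=n_samples)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def reduced_scale_params(Z: int, Nm: int = 16, E: float = 1.0, seed: int = 0,
                         **overrides) -> SimulationParameters:
    """Desk-scale study conditions: small box, short chain, matched physics.

    Interaction parameters are the full-scale ones; only the extensive
    quantities shrink: box (60, 16, 16) sigma, 16 salt molecules, and a
    30 tu constrained relaxation (an 11-bead Rouse chain decorrelates in a
    few tu).
    """
    defaults = dict(Z=Z, Nm=Nm, E=E, seed=seed, box=(60.0, 16.0, 16.0),
                    n_salt=16, relax_time=30.0, coulomb_cutoff=7.5)
    defaults.update(overrides)
    return SimulationParameters(**defaults)
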