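"""Physical model: parameters, particle system and interaction potentials.

Reduced simulation units are used throughout: length :math:`\\sigma`,
energy :math:`k_BT`, charge :math:`e`, mass :math:`m` (all mobile beads have
unit mass) and time :math:`t_u = \\sigma\\sqrt{m/k_BT}`.  The driving-field
unit is :math:`E_u = k_BT/(e\\sigma)`.

The model is a coarse-grained bead-spring polyelectrolyte: every monomer
carries charge ``-e`` and releases one monovalent counterion; added
(Z:1)-salt dissociates into one ``+Z`` cation and ``Z`` monovalent anions.
A membrane slab pierced by a cylindrical pore divides the periodic box into
a *cis* and a *trans* compartment along ``x``; a uniform electric field
``-E x̂`` acts on every charge inside the pore channel.

Interactions are the purely repulsive Weeks-Chandler-Andersen (WCA)
excluded volume, the bare Coulomb pair energy
:math:`u(r) = k_BT\\,\\lambda_B Z_i Z_j / r` (summed by a configurable
solver), and stiff harmonic bonds along the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

from .errors import ConfigError, OverlapError

WCA_CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)

# species codes used in ParticleSystem.species
MONOMER = 0
CHAIN_COUNTERION = 1
SALT_CATION = 2
SALT_ANION = 3
WALL_BEAD = 4
ANCHOR = 5

SPECIES_NAMES = {
    MONOMER: "monomer",
    CHAIN_COUNTERION: "chain_counterion",
    SALT_CATION: "salt_cation",
    SALT_ANION: "salt_anion",
    WALL_BEAD: "wall_bead",
    ANCHOR: "anchor",
}

_ELECTROSTATICS_MODES = ("dsf", "ewald", "none")


@dataclass
class SimulationParameters:
    """Full physical and numerical configuration of one translocation system.

    Parameters mirror the bead-spring nanopore model: a chain of ``Nm``
    monomers threaded through a pore of radius ``pore_radius`` in a membrane
    slab of thickness ``wall_thickness``, with explicit counterions and
    ``n_salt`` molecules of (Z:1)-salt, driven by a field of strength ``E``
    (in :math:`k_BT/(e\\sigma)`) applied inside the pore channel.

    ``Z`` must always be stated explicitly; there is no default salt valence.
    """

    Z: int
    Nm: int = 128
    E: float = 0.5
    box: tuple = (200.0, 48.0, 49.4)
    wall_thickness: float = 4.5
    pore_radius: float = 2.25
    lambda_B: float = 3.0
    eps_pp: float = 1.2
    sigma_pp: float = 1.0
    eps_pw: float = 2.5
    sigma_pw: float = 1.5
    k_bond: float = 600.0
    b0: float = 1.0
    n_salt: int = 256
    damping_time: float = 1.0
    dt: float = 0.005
    seed: int = 0
    electrostatics_mode: str = "dsf"
    # None -> auto: min(10, min(box)/2 - 0.1)
    coulomb_cutoff: Optional[float] = None
    # None -> auto: 1.0 / coulomb_cutoff  (damping of the shifted-force sum;
    # weak damping suits these dilute, strongly screened systems)
    dsf_alpha: Optional[float] = None
    # None -> auto: 50 * N**1.2 tu under the head constraint
    relax_time: Optional[float] = None
    # None -> auto: 1e4 * N tu
    max_time: Optional[float] = None
    wall: bool = True              # analytic membrane slab + pore
    explicit_wall: bool = False    # immobile-bead wall on a cubic lattice
    excluded_volume: bool = True
    neutral_chain: bool = False    # uncharged chain, no counterions (controls)
    barrier_eps: float = 1.2
    barrier_sigma: float = 1.0

    def __post_init__(self):
        if self.Z not in (1, 2):
            raise ConfigError(f"Z must be 1 or 2, got {self.Z}", key="Z")
        if self.Nm < 6:
            raise ConfigError("Nm must be >= 6 (five monomers prime the pore)",
                              key="Nm")
        if self.E < 0:
            raise ConfigError("E must be >= 0", key="E")
        self.box = tuple(float(v) for v in self.box)
        if len(self.box) != 3:
            raise ConfigError("box must have three sides", key="box")
        positive = ("wall_thickness", "pore_radius", "lambda_B", "eps_pp",
                    "sigma_pp", "eps_pw", "sigma_pw", "k_bond", "b0",
                    "damping_time", "dt", "barrier_eps", "barrier_sigma")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive", key=name)
        if any(side <= 0 for side in self.box):
            raise ConfigError("box sides must be strictly positive", key="box")
        if self.n_salt < 0:
            raise ConfigError("n_salt must be >= 0", key="n_salt")
        if self.pore_radius >= min(self.box[1], self.box[2]) / 2:
            raise ConfigError("pore_radius must be < min(Ly, Lz)/2",
                              key="pore_radius")
        if self.dt >= self.damping_time:
            raise ConfigError("dt must be smaller than the damping time",
                              key="dt")
        if self.electrostatics_mode not in _ELECTROSTATICS_MODES:
            raise ConfigError(
                f"electrostatics_mode must be one of {_ELECTROSTATICS_MODES}",
                key="electrostatics_mode")

    # ---- derived quantities -------------------------------------------------

    @property
    def N(self) -> int:
        """Monomers transported from the cis side (five prime the pore)."""
        return self.Nm - 5

    @property
    def half_wall(self) -> float:
        return self.wall_thickness / 2.0

    @property
    def x_exit(self) -> float:
        """Trans-side face of the membrane: location of the head barrier."""
        return self.half_wall

    @property
    def gamma(self) -> float:
        """Langevin friction coefficient, m / damping_time."""
        return 1.0 / self.damping_time

    def resolved_coulomb_cutoff(self) -> float:
        if self.coulomb_cutoff is not None:
            return float(self.coulomb_cutoff)
        return min(10.0, min(self.box) / 2.0 - 0.1)

    def resolved_dsf_alpha(self) -> float:
        if self.dsf_alpha is not None:
            return float(self.dsf_alpha)
        return 1.0 / self.resolved_coulomb_cutoff()

    def resolved_relax_time(self) -> float:
        if self.relax_time is not None:
            return float(self.relax_time)
        return 50.0 * self.N ** 1.2

    def resolved_max_time(self) -> float:
        if self.max_time is not None:
            return float(self.max_time)
        return 1.0e4 * self.N

    def replace(self, **kwargs) -> "SimulationParameters":
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls):
        return [f.name for f in fields(cls)]


@dataclass
class ParticleSystem:
    """Evolving state: positions, velocities, charges, species and topology.

    Coordinates live in the centred box ``[-L/2, L/2)`` in each direction;
    the membrane mid-plane is ``x = 0``.  Wall beads and anchors are
    immobile (``mobile`` False) and keep zero velocity at all times.
    """

    positions: np.ndarray
    velocities: np.ndarray
    charges: np.ndarray
    species: np.ndarray
    bonds: np.ndarray
    box: np.ndarray
    mobile: np.ndarray
    head_index: int = 0

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            charges=self.charges.copy(),
            species=self.species.copy(),
            bonds=self.bonds.copy(),
            box=self.box.copy(),
            mobile=self.mobile.copy(),
            head_index=self.head_index,
        )

    def total_charge(self) -> float:
        return float(self.charges.sum())

    def monomer_indices(self) -> np.ndarray:
        return np.flatnonzero(self.species == MONOMER)

    def region_counts(self, half_wall: float) -> tuple:
        """(cis, pore, trans) monomer counts; cis x < -w/2, trans x > +w/2."""
        x = self.positions[self.monomer_indices(), 0]
        cis = int(np.sum(x < -half_wall))
        trans = int(np.sum(x > half_wall))
        pore = x.size - cis - trans
        return cis, pore, trans

    def kinetic_temperature(self) -> float:
        """Instantaneous kinetic temperature of the mobile particles."""
        v = self.velocities[self.mobile]
        if v.size == 0:
            return 0.0
        return float(np.mean(v ** 2))  # m = kB = 1

    def unwrapped_chain(self) -> np.ndarray:
        """Monomer coordinates unwrapped by walking minimum images along bonds."""
        idx = self.monomer_indices()
        pos = self.positions[idx]
        L = self.box
        out = np.empty_like(pos)
        out[0] = pos[0]
        for k in range(1, len(idx)):
            d = pos[k] - pos[k - 1]
            d -= L * np.round(d / L)
            out[k] = out[k - 1] + d
        return out


# ---- pure potential evaluations ---------------------------------------------


def wca_energy(r, sigma_ij: float = 1.0, eps_ij: float = 1.0):
    """Weeks-Chandler-Andersen energy: truncated-shifted LJ, purely repulsive.

    ``U(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps`` for
    ``r <= 2^(1/6) sigma`` and zero beyond; continuous at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r == 0):
        raise OverlapError("WCA energy diverges at r = 0 (overlapping beads)")
    cutoff = WCA_CUTOFF_FACTOR * sigma_ij
    sr6 = (sigma_ij / r) ** 6
    u = np.where(r <= cutoff, 4.0 * eps_ij * (sr6 ** 2 - sr6) + eps_ij, 0.0)
    return u if u.ndim else float(u)


def wca_force(r, sigma_ij: float = 1.0, eps_ij: float = 1.0):
    """Radial WCA force magnitude ``-dU/dr`` (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r == 0):
        raise OverlapError("WCA force diverges at r = 0 (overlapping beads)")
    cutoff = WCA_CUTOFF_FACTOR * sigma_ij
    sr6 = (sigma_ij / r) ** 6
    f = np.where(r <= cutoff, 24.0 * eps_ij * (2.0 * sr6 ** 2 - sr6) / r, 0.0)
    return f if f.ndim else float(f)


def coulomb_energy(r, Zi: float, Zj: float, lambda_B: float = 3.0):
    """Bare Coulomb pair energy ``kBT * lambda_B * Zi * Zj / r``."""
    r = np.asarray(r, dtype=float)
    if np.any(r == 0):
        raise OverlapError("Coulomb energy diverges at r = 0")
    u = lambda_B * Zi * Zj / r
    return u if u.ndim else float(u)


def bond_energy(b, k: float = 600.0, b0: float = 1.0):
    """Harmonic bond energy ``(k/2)(b - b0)^2``."""
    b = np.asarray(b, dtype=float)
    u = 0.5 * k * (b - b0) ** 2
    return u if u.ndim else float(u)


def in_pore_region(position, params: SimulationParameters) -> bool:
    """True if a point lies inside the pore channel (cylinder within slab)."""
    x, y, z = position
    if abs(x) > params.half_wall:
        return False
    return math.hypot(y, z) < params.pore_radius


def pore_field_force(position, charge: float,
                     params: SimulationParameters) -> np.ndarray:
    """Driving force on a charge inside the pore channel.

    The field is uniform, ``E_vec = -E x̂``, confined to the pore cylinder,
    so a ``-e`` monomer is pushed toward ``+x`` (cis -> trans).
    """
    f = np.zeros(3)
    if in_pore_region(position, params) and params.E != 0.0:
        f[0] = -charge * params.E
    return f


def wall_surface_distance(position, params: SimulationParameters) -> float:
    """Distance from a point to the membrane material (slab minus pore).

    The material occupies ``|x| <= w/2`` and ``sqrt(y^2+z^2) >= R``; the
    closest-point distance has the closed form
    ``sqrt(max(0, |x|-w/2)^2 + max(0, R - r)^2)``.
    """
    x, y, z = position
    dx = max(0.0, abs(x) - params.half_wall)
    dr = max(0.0, params.pore_radius - math.hypot(y, z))
    return math.hypot(dx, dr)


def total_energy(system: ParticleSystem, params: SimulationParameters) -> float:
    """Total potential energy of a system under the selected solver."""
    from .simulate import forces_and_energy

    _, u = forces_and_energy(system, params)
    return u
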