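# Methods

## Model

The polyelectrolyte is a bead-spring chain of `Nm` monomers, each carrying
charge −e and releasing one monovalent counterion; added (Z:1)-salt
dissociates into one +Z cation and Z monovalent anions, so every system is
exactly charge neutral by construction. Reduced units are used throughout:
length σ, energy kBT, charge e, bead mass m = 1, time tu = σ√(m/kBT), and
field unit Eu = kBT/(eσ).

Interactions:

* **Excluded volume** — the WCA potential
  `U = 4ε[(σij/r)¹² − (σij/r)⁶] + ε` for r ≤ 2^(1/6)σij, zero beyond, with
  σpp = 1.0σ, εpp = 1.2 kBT between mobile beads and σpw = 1.5σ,
  εpw = 2.5 kBT between mobile beads and the wall.
* **Electrostatics** — pair energy kBT·λB·ZiZj/r with Bjerrum length
  λB = 3.0σ, summed by a configurable solver (below).
* **Bonds** — harmonic, `U = (k/2)(b − b0)²` with k = 600 kBT/σ² and
  b0 = 1.0σ. Bonded pairs also interact through WCA and Coulomb (no
  exclusions), as is standard for bead-spring polyelectrolytes.

The membrane is a slab of thickness 4.5σ centred at x = 0, pierced by a
cylindrical pore of radius 2.25σ along x̂. The default wall is analytic: the
closest-point distance to the wall material
`d = √(max(0,|x|−w/2)² + max(0,R−r⊥)²)` enters a WCA repulsion with
(σpw, εpw). This preserves the stated geometry and contact distances of a
bead-built wall at far lower cost; an explicit immobile-bead wall on a cubic
lattice (spacing 1σ) is available via `explicit_wall = true` for visual
fidelity. The box (default 200.0 × 48.0 × 49.4 σ) is periodic in all three
directions.

Inside the pore channel (the cylinder r⊥ < R, |x| ≤ w/2) a uniform field
`E⃗ = −E x̂` acts on **every** charge, so monomers (−e) drift cis → trans
while cations drift the other way. For energy bookkeeping the field is given
the potential `q E clamp(x, −w/2, w/2)` for particles inside the cylinder,
which makes forces exact negative gradients away from the (measure-zero)
cylinder surface.

A one-sided repulsive barrier — a WCA wall diverging at the pore-exit plane
x = +w/2 — acts on the head monomer only, so the head can never re-enter the
pore and complete retraction to the cis side is impossible. All other
monomers are free to shuttle back and forth through the pore.

## Electrostatics solvers

`electrostatics_mode` selects:

* `dsf` (default) — damped shifted-force real-space Coulomb with cutoff
  rc (default min(10σ, L/2)) and damping α (default 1/rc), plus the Wolf
  self term so that energies are comparable to Ewald. Energy and force both
  go continuously to zero at rc.
* `ewald` — classical Ewald summation (real + reciprocal + self, tinfoil
  boundary), implemented in vectorised numpy and validated against the NaCl
  Madelung constant to 10⁻⁵. It serves as the reference for energies/forces;
  dynamics runs use `dsf` or `none`.
* `none` — electrostatics off (controls).

On compact neutral ion clusters whose pairs all lie inside the cutoff, DSF
forces agree with Ewald to ≈1–2%. On the production translocation boxes the
RMS force deviation is ≈15–30%: the boxes are small (the chain spans a
significant fraction of the cell) and the missing periodic-image/long-range
contribution is genuine. The deviation is nearly independent of α, confirming
it is a cutoff effect, not a damping artefact; weak damping (α·rc = 1) sits
at the shallow error minimum and is the default. The DSF approximation
therefore preserves the screening physics (divalent condensation, chain
compaction) — verified behaviourally by the salt-valence orderings of the
tethered- and free-chain profiles — but is not a quantitative substitute for
a mesh Ewald solver at full scale.

## Integrator and thermostat

Velocity-Verlet with the Langevin thermostat applied as a force:
`F = F_cons − γ m v + R(t)` with γ = m/damping_time (default damping time
1.0 tu) and R drawn per step with per-component variance 2γ m kBT/dt
(fluctuation–dissipation). dt defaults to 0.005 tu: the stiffest mode is the
bond oscillation with period 2π√(m/k) ≈ 0.26 tu, i.e. ≥ 50 steps/period.
With the thermostat on, the kinetic temperature of an interacting system
holds 1 kBT within 0.1%; with γ → 0 the scheme reduces to plain
velocity-Verlet and drifts < 10⁻³ kBT/tu on a small test system. A per-step
displacement larger than 0.5σ raises an instability error advising a smaller
timestep.

The thermostat noise is drawn from a seeded PCG64 generator outside the
compiled kernel; a run is bitwise reproducible from its seed, and batch runs
use seeds seed0, seed0+1, … so that every run is independently reproducible.

## Translocation protocol

The initial state threads the chain through the pore: the head monomer
(index 1) is placed at barrier contact just beyond the exit, monomers 2–5
run back through the channel at ≈1.02σ spacing, and the remaining chain is
grown into the cis compartment by a biased self-avoiding walk. With b0 = 1σ
bonds, four bond lengths cannot span the 4.5σ channel from the barrier
contact point to the cis entrance, so the five "primer" monomers occupy the
channel from the exit side and monomer 6 is the first cis-side monomer.
Counterions and salt are inserted uniformly (outside the wall, without
overlaps). The system is then relaxed with the head held fixed and the field
off (default 50·N^1.2 tu, configurable), and the run starts by releasing the
head and switching the field on simultaneously.

The translocation coordinate n(t) counts trans-side monomers beyond the five
primers, `n = max(0, #trans − 5)`, so a completed run ends exactly at
N = Nm − 5, the number of monomers actually transported from the cis side.
n(t) need not be monotone — the dynamics is drift-diffusive. A monomer is
cis if x < −w/2, trans if x > +w/2, else in-pore, so the three counts
partition the chain exactly.

Because the dynamics is diffusive, τ is **not** a first-passage time: it is
the last time any monomer occupies the cis region, evaluated once the whole
chain is on the trans side and its centre of mass is at least one radius of
gyration beyond the wall (hysteresis margin), after which a return is no
longer possible in practice. Runs that hit `max_time` (default 10⁴·N tu) are
flagged `max_time_reached`, excluded from ⟨τ⟩ and reported, never silently
dropped.

## Static samplers

*Tethered chain*: the chain is anchored to the trans wall face by a harmonic
bond to a fixed virtual anchor; ⟨Rm⟩ is the mean distance of monomer m to
the anchor, so ⟨R1⟩ ≈ b0 and the estimator νs0(m) = log(⟨Rm⟩/⟨R1⟩)/log m is
well defined (m = 1 is excluded since log 1 = 0). *Free chain*: no wall;
⟨Rij⟩ is averaged over all monomer pairs at fixed bond separation and over
snapshots, and νb0(s) = log(⟨Rij⟩/⟨R_{s=1}⟩)/log s. Chain coordinates are
unwrapped by walking minimum images along bonds, so distances are true
distances even when the chain outgrows the periodic cell.

## Estimators

⟨τ⟩ averages completed runs; pairwise exponents use adjacent points on the
log-log curve, `sign·log(y₂/y₁)/log(x₂/x₁)`, reported at the geometric mean
√(x₁x₂) (sign − for δ on (E, ⟨τ⟩), + for α on (N, ⟨τ⟩)); multi-point fits
use ordinary least squares on (log x, log y). The variance curve
⟨Δn²⟩(t/⟨τ⟩) resamples every run's step-function n(t) by
last-observation-carried-forward onto a common normalized-time grid and
takes the across-run population variance; it is exactly zero wherever all
runs coincide and falls to zero once every run has completed. γ is the
log-log slope over a stated window; the early-time window (default
t/⟨τ⟩ ∈ [0.01, 0.1]) gives the subdiffusion exponent γp, and the window is
recorded on every estimate.

All five estimators recover noiselessly planted power laws to 10⁻¹⁰.

## Synthetic trajectory generator

`generate_synthetic_trajectories` produces ensembles with planted dynamics
without MD: an integer-valued biased random walk on [0, N] (reflecting at 0,
absorbing at N) in an internal clock s, with per-step probabilities chosen so
the drift is `drift` and the variance grows as 2·diffusion·s, subordinated to
physical time t = s^(1/γ) so the ensemble variance grows as t^γ. The
deterministic special case (diffusion = 0) gives τ = N/drift exactly with
zero variance; the unbiased case reproduces the exact first-step-analysis
mean absorption time (solved as a linear system — the independent oracle).
What the generator emulates is the drift-diffusion phenomenology of n(t);
it has no chain conformations, no tension propagation and no salt physics,
so estimator tests on it validate the *analysis pipeline*, not the
molecular model. Near the reflecting boundary and near absorption the
planted variance law is distorted, so planted-γ recovery is checked in a
window clear of both.

## Tension-front integration

`solve_tension_ode` integrates the reduced propagation balance
`d/dt [R^a − R² f^(−pz·q)] = f^(pz(1−q))`, a = 1/νs − q + 1, by numeric
quadrature of dR/dt from R₀ = 1 to R = N^νs (the isoflux variant integrates
`d/dt [R^(1/νs+1) − R²] = f`). The fitted asymptotic slopes reproduce
1 + νs(1−q) in N and −pz(1−q) in f within 2%, and dropping the subleading
R² term changes τp by < 1% at large f.

## Exponent inversion and reporting

`invert_observed` solves νs = α_SD(I) − 1, q = 1 − (α_SD(T) − 1)/νs and
zp = (α_UB − 2)/(νs(1 − γp)) at full precision. The boundary exponents
ρ = (zp(1−γp) − 1 + q)/(δ_SD(T) − 1) and η = q/(δ_SD(T) − 1) follow the
reporting convention of tabulated exponent chains: they are evaluated from
the **two-decimal reported** intermediates, so the derived column is exactly
reproducible from printed values (the fully unrounded chain is exposed as
`rho_raw`/`eta_raw`; for the monovalent case it gives 1.49 versus the
reported 1.50). All reporting uses decimal half-up rounding, applied only at
the reporting boundary.

## Reduced-scale study conditions

Full-scale production parameters (box 200 × 48 × 49.4 σ, 256 salt molecules,
chains to Nm = 384, ≥500 runs per state point) are available through the
config, but the test suite and behavioural checks run a reduced preset
chosen once: Nm = 16, box 60 × 16 × 16 σ, 16 salt molecules (same order of
salt concentration), Coulomb cutoff 7.5σ, and a 30 tu constrained relaxation
— an 11-bead Rouse chain decorrelates in ≈ 4 tu, so this is a comfortable
margin while the full-scale default (50·N^1.2 tu) remains for long chains.
At this scale the simulator resolves the robust qualitative signatures
(strict decrease of ⟨τ⟩ with E, δ ≈ 1 in the drift regime, salt-valence
ordering of chain sizes, completed runs transporting exactly Nm − 5), but
not the asymptotic exponent surfaces, which require the full-scale ensemble;
the closed-form theory layer carries those exactly.

## Numerical choices and degenerate inputs

* Insertion clearances: 0.95σ between particles, 1.55σ from the wall
  surface; bounded retries raise a packing error.
* r = 0 in any pair potential raises an overlap error; ρ/η are singular at
  pz(1−q) = 1, zp at γp = 1 — all raised explicitly with the parameter named.
* Theory curves carry an undetermined global prefactor; continuity at each
  regime boundary fixes the shape and a caller-supplied anchor fixes the
  scale. Boundary ordering requires f < 1 (forces in kBT/b); the curve
  builder raises if the boundaries are not ordered.
* `derived_relations` never overwrites a user-given exponent: residuals of
  over-determined relations are reported, and residuals beyond 0.05 raise.

## Known limitations

* No hydrodynamics (Rouse dynamics only), no electroosmotic flow, no charged
  wall, no dielectric discontinuity or image charges, and the field is
  strictly confined to the pore cylinder — the far-field funnel of a real
  pore is absent.
* The DSF solver underestimates long-range electrostatics in small boxes
  (quantified above).
* Desk-scale ensembles cannot reach the long-chain scaling limit; exponent
  estimates from the reduced preset are illustrative, not asymptotic.
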