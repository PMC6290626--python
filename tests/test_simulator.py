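"""Builders, Langevin integrator and the translocation protocol."""

import numpy as np
import pytest
from conftest import make_bare_system

from poretrans.errors import InstabilityError
from poretrans.model import (CHAIN_COUNTERION, MONOMER, SALT_ANION,
                             SALT_CATION, WALL_BEAD, SimulationParameters)
from poretrans.simulate import (_advance, build_initial_state,
                                forces_and_energy, langevin_step,
                                reduced_scale_params, run_batch,
                                run_translocation, wall_bead_positions)


class TestBuilder:
    def test_divalent_species_counts_and_neutrality(self):
        # full-scale composition: Nm monomers (-1), Nm counterions (+1),
        # n_salt cations (+2), 2 n_salt anions (-1)
        p = SimulationParameters(Z=2, Nm=128, n_salt=256, E=0.5, seed=1)
        s = build_initial_state(p, relax=False)
        counts = {k: int(np.sum(s.species == k))
                  for k in (MONOMER, CHAIN_COUNTERION, SALT_CATION,
                            SALT_ANION)}
        assert counts == {MONOMER: 128, CHAIN_COUNTERION: 128,
                          SALT_CATION: 256, SALT_ANION: 512}
        assert s.total_charge() == 0.0

    def test_monovalent_neutrality(self):
        p = reduced_scale_params(Z=1, Nm=16, seed=2)
        s = build_initial_state(p, relax=False)
        assert s.total_charge() == 0.0

    def test_initial_threading_geometry(self):
        p = reduced_scale_params(Z=1, Nm=16, seed=3)
        s = build_initial_state(p, relax=False)
        hw = p.half_wall
        x = s.positions[s.monomer_indices(), 0]
        # head just beyond the pore exit, never behind the barrier plane
        assert x[0] > hw
        # the first five monomers run from the exit back through the channel
        assert x[:5].min() < 0.0 < x[:5].max()
        assert np.all(np.diff(x[:5]) < 0)
        # the chain body reaches the cis compartment
        assert x.min() < -hw

    def test_same_seed_bitwise_identical(self):
        p = reduced_scale_params(Z=2, Nm=16, seed=7)
        a = build_initial_state(p, relax=False)
        b = build_initial_state(p, relax=False)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_explicit_wall_lattice_excludes_pore(self):
        p = reduced_scale_params(Z=1, Nm=16, seed=1, explicit_wall=True)
        pts = wall_bead_positions(p)
        assert np.all(np.hypot(pts[:, 1], pts[:, 2]) >= p.pore_radius)
        assert np.all(np.abs(pts[:, 0]) < p.half_wall)


class TestIntegrator:
    def test_free_particle_equipartition(self):
        p = SimulationParameters(Z=1, E=0.0, wall=False, n_salt=0,
                                 electrostatics_mode="none", box=(20, 20, 20))
        s = make_bare_system([[0.0, 0.0, 0.0]], [0.0], p.box)
        rng = np.random.default_rng(0)
        _advance(s, p, rng, 2000, field_on=False)  # thermalise
        acc = 0.0
        n_blocks = 500
        for _ in range(n_blocks):
            _advance(s, p, rng, 200, field_on=False)
            acc += np.mean(s.velocities[0] ** 2)
        assert acc / n_blocks == pytest.approx(1.0, abs=0.12)

    def test_symplectic_limit_energy_drift(self):
        p = SimulationParameters(Z=1, Nm=8, E=0.0, box=(40., 14., 14.),
                                 n_salt=4, damping_time=1e9,
                                 coulomb_cutoff=6.0, seed=2)
        s = build_initial_state(p, relax=False)
        s.velocities[s.mobile] = np.random.default_rng(0).normal(
            0, 0.3, s.velocities[s.mobile].shape)
        rng = np.random.default_rng(1)

        def etot():
            _, u = forces_and_energy(s, p, field_on=False)
            return u + 0.5 * np.sum(s.velocities[s.mobile] ** 2)

        e0 = etot()
        _advance(s, p, rng, 2000, field_on=False)   # 10 tu
        assert abs(etot() - e0) / 10.0 < 1e-3

    def test_kinetic_temperature_control(self):
        p = reduced_scale_params(Z=1, Nm=16, E=0.0, seed=7)
        s = build_initial_state(p, relax=False)
        rng = np.random.default_rng(1)
        _advance(s, p, rng, 2000, field_on=False)
        temps = []
        for _ in range(100):
            _advance(s, p, rng, 100, field_on=False)
            temps.append(s.kinetic_temperature())
        assert np.mean(temps) == pytest.approx(1.0, abs=0.02)

    def test_fixed_seed_reproducible_trajectory(self):
        p = reduced_scale_params(Z=1, Nm=12, E=2.0, seed=5)
        a = build_initial_state(p, relax=False)
        b = a.copy()
        for rng, s in ((np.random.default_rng(3), a),
                       (np.random.default_rng(3), b)):
            for _ in range(10):
                langevin_step(s, p, rng)
        assert np.array_equal(a.positions, b.positions)

    def test_instability_raises_with_advice(self):
        p = SimulationParameters(Z=1, Nm=8, E=0.0, box=(40., 14., 14.),
                                 n_salt=0, dt=0.2, seed=3)
        s = build_initial_state(p, relax=False)
        rng = np.random.default_rng(0)
        with pytest.raises(InstabilityError, match="dt"):
            _advance(s, p, rng, 500, field_on=False)

    def test_periodic_translation_leaves_trajectory_invariant(self):
        p = reduced_scale_params(Z=1, Nm=12, E=2.0, seed=8)
        a = build_initial_state(p, relax=False)
        b = a.copy()
        # shift by one lattice vector and re-wrap; the re-wrapped state is
        # equal up to float round-off of the add/subtract, so the two
        # trajectories must stay together over a short run
        b.positions[:, 1] += b.box[1]
        b.positions[:, 1] -= b.box[1] * np.round(b.positions[:, 1] / b.box[1])
        _advance(a, p, np.random.default_rng(5), 200, field_on=True)
        _advance(b, p, np.random.default_rng(5), 200, field_on=True)
        assert np.allclose(a.positions, b.positions, atol=1e-6)

    def test_wall_beads_stay_immobile(self):
        p = reduced_scale_params(Z=1, Nm=12, E=1.0, seed=6,
                                 explicit_wall=True)
        s = build_initial_state(p, relax=False)
        wall = s.species == WALL_BEAD
        ref = s.positions[wall].copy()
        _advance(s, p, np.random.default_rng(2), 100, field_on=True)
        assert np.array_equal(s.positions[wall], ref)
        assert np.all(s.velocities[wall] == 0.0)


class TestHeadBarrier:
    def test_head_never_crosses_exit_plane(self):
        p = reduced_scale_params(Z=1, Nm=16, E=4.0, seed=9)
        s = build_initial_state(p, relax=True)
        rng = np.random.default_rng(11)
        min_head = np.inf
        below_exit = False
        for _ in range(150):
            _advance(s, p, rng, 20, field_on=True)
            min_head = min(min_head, s.positions[0, 0])
            others = s.positions[s.monomer_indices()[1:], 0]
            below_exit |= bool(np.any(others < p.x_exit))
        assert min_head >= p.x_exit
        # monomers other than the head do visit the pore / cis side
        assert below_exit

    def test_barrier_force_zero_beyond_cutoff(self):
        p = SimulationParameters(Z=1, E=0.0, wall=False, n_salt=0,
                                 electrostatics_mode="none")
        cut = 2 ** (1 / 6) * p.barrier_sigma
        far = make_bare_system([[p.x_exit + cut + 0.05, 0, 0]], [0.0],
                               p.box, head_index=0)
        F, _ = forces_and_energy(far, p)
        assert np.all(F == 0.0)
        near = make_bare_system([[p.x_exit + 0.5, 0, 0]], [0.0],
                                p.box, head_index=0)
        F2, _ = forces_and_energy(near, p)
        assert F2[0, 0] > 0.0


class TestTranslocationRuns:
    def test_completed_run_transports_Nm_minus_5(self):
        p = reduced_scale_params(Z=1, Nm=16, E=8.0, seed=3)
        ev = run_translocation(p)
        assert ev.completed
        assert ev.n_series[-1] == p.Nm - 5
        assert ev.N == p.Nm - 5
        assert np.all((ev.n_series >= 0) & (ev.n_series <= ev.N))
        assert ev.tau > 0

    def test_counts_partition_during_run(self):
        p = reduced_scale_params(Z=2, Nm=16, E=2.0, seed=4)
        s = build_initial_state(p, relax=True)
        rng = np.random.default_rng(0)
        for _ in range(30):
            _advance(s, p, rng, 50, field_on=True)
            cis, pore, trans = s.region_counts(p.half_wall)
            assert cis + pore + trans == p.Nm
            assert s.total_charge() == 0.0

    def test_zero_field_translocation_still_completes(self):
        # with the head barrier, translocation proceeds by random walk
        p = reduced_scale_params(Z=1, Nm=8, E=0.0, seed=2, max_time=5000.0)
        ev = run_translocation(p)
        assert ev.completed

    def test_batch_seeds_and_reproducibility(self):
        p = reduced_scale_params(Z=1, Nm=16, E=8.0)
        a = run_batch(p, 3, seed0=50)
        b = run_batch(p, 3, seed0=50)
        assert [ev.seed for ev in a] == [50, 51, 52]
        for ea, eb in zip(a, b):
            assert ea.tau == eb.tau
            assert np.array_equal(ea.n_series, eb.n_series)

    def test_failed_runs_flagged_not_dropped(self):
        p = reduced_scale_params(Z=1, Nm=16, E=0.05, seed=1)
        events = run_batch(p, 2, seed0=0, max_time=2.0)  # far too short
        assert len(events) == 2
        assert all(ev.status == "max_time_reached" for ev in events)
        assert all(np.isnan(ev.tau) for ev in events)
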