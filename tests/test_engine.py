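"""DPD engine: pair forces, integrator, thermostat, neighbour search."""

import numpy as np
import pytest

from dpdgel.engine import (
    Protocol, bond_force, compute_forces, conservative_force,
    dissipative_force, instantaneous_temperature, integrate_step,
    maxwell_boltzmann_velocities, neighbor_search, random_force,
    run_simulation, state_from_configuration, SimulationState,
)
from dpdgel.errors import BlowUpError, DomainError, GeometryError
from dpdgel.forcefield import build_forcefield
from dpdgel.topology import InitialConfiguration


class TestPairForces:
    def test_conservative_linear_ramp(self):
        assert conservative_force(1.0, 80.0) == 0.0
        assert conservative_force(0.0, 80.0) == 80.0
        assert conservative_force(0.5, 80.0) == pytest.approx(40.0)
        assert conservative_force(1.5, 80.0) == 0.0

    def test_dissipative_projection(self):
        rhat = np.array([1.0, 0.0, 0.0])
        perp = np.array([0.0, 2.0, 0.0])
        assert np.allclose(dissipative_force(0.5, rhat, perp, 4.5), 0.0)
        along = 3.0 * rhat
        f = dissipative_force(0.5, rhat, along, 4.5)
        assert np.allclose(f, -4.5 * 3.0 * rhat)
        assert np.allclose(dissipative_force(1.2, rhat, along, 4.5), 0.0)

    def test_dissipative_zero_separation_rejected(self):
        with pytest.raises(DomainError):
            dissipative_force(0.0, np.array([1.0, 0, 0]), np.zeros(3), 4.5)

    def test_random_force_statistics(self):
        # theta is uniform with zero mean, unit variance
        rng = np.random.default_rng(0)
        rhat = np.array([1.0, 0.0, 0.0])
        n = 100_000
        samples = np.array([
            random_force(0.5, rhat, 3.0, 0.01, rng)[0] / (3.0 / np.sqrt(0.01))
            for _ in range(n)
        ])
        assert abs(samples.mean()) < 3.0 / np.sqrt(n)
        assert samples.var() == pytest.approx(1.0, rel=0.02)
        assert np.abs(samples).max() <= np.sqrt(3.0) + 1e-12

    def test_random_force_pair_antisymmetry(self):
        # the same draw with opposite sign acts on the partner
        rng = np.random.default_rng(1)
        rhat = np.array([0.0, 1.0, 0.0])
        f_i = random_force(0.5, rhat, 3.0, 0.01, rng)
        assert np.allclose(f_i + (-f_i), 0.0)

    def test_bond_force_hooke(self):
        params = (57.0, 0.85)
        assert bond_force(0.85, params) == 0.0
        assert bond_force(0.95, params) == pytest.approx(-5.7)
        assert bond_force(0.75, params) == pytest.approx(+5.7)


class TestIntegration:
    def test_isolated_resting_beads_stay_put(self, ff_ambient):
        init = InitialConfiguration(
            box_side=5.0,
            positions=np.array([[1.0, 1.0, 1.0], [3.5, 1.0, 1.0]]),
            types=np.zeros(2, dtype=np.int64),
            bonds=np.empty((0, 2), dtype=np.int64), n_polymer=0, n_water=2)
        st = state_from_configuration(init, ff_ambient, seed=0)
        st.velocities[:] = 0.0
        for _ in range(5):
            integrate_step(st, ff_ambient, dt=0.01)
        assert np.allclose(st.positions, init.positions)
        assert np.allclose(st.velocities, 0.0)

    def test_momentum_conservation(self, ff_ambient, water_box_factory):
        from dpdgel import _kernels
        init, st = water_box_factory(500, seed=3)
        p0 = (st.masses[:, None] * st.velocities).sum(axis=0)
        bad = _kernels.run_dpd_block(
            st.positions, st.images, st.velocities, st.types, st.masses,
            st.box_side, ff_ambient.fmax_matrix(), ff_ambient.gamma,
            ff_ambient.sigma, init.bonds, 0.0, 0.0, 0.01, 10_000, 0, 3,
            _kernels.MODE_DPD, 1.0, 0.3)
        assert bad < 0
        p1 = (st.masses[:, None] * st.velocities).sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-8 * st.n_beads

    def test_thermostat_temperature(self, ff_ambient, water_box_factory):
        from dpdgel import _kernels
        init, st = water_box_factory(500, seed=4)
        temps = []
        for block in range(50):
            _kernels.run_dpd_block(
                st.positions, st.images, st.velocities, st.types, st.masses,
                st.box_side, ff_ambient.fmax_matrix(), ff_ambient.gamma,
                ff_ambient.sigma, init.bonds, 0.0, 0.0, 0.01, 1_000,
                block * 1_000, 4, _kernels.MODE_DPD, 1.0, 0.3)
            if block >= 10:
                temps.append(instantaneous_temperature(st))
        assert np.mean(temps) == pytest.approx(1.0, abs=0.02)

    def test_blow_up_detected_with_step_index(self, ff_ambient):
        init = InitialConfiguration(
            box_side=5.0, positions=np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]]),
            types=np.zeros(2, dtype=np.int64),
            bonds=np.empty((0, 2), dtype=np.int64), n_polymer=0, n_water=2)
        st = state_from_configuration(init, ff_ambient, seed=0)
        st.velocities[0] = 1e6
        with pytest.raises(BlowUpError) as err:
            integrate_step(st, ff_ambient, dt=0.01)
        assert err.value.step == 0

    def test_deterministic_trajectories(self, ff_ambient, water_box_factory):
        protocol = Protocol(pre_thermalization_steps=200,
                            thermalization_steps=200, production_steps=600,
                            snapshot_interval=200, seed=11)
        init, _ = water_box_factory(120, seed=11)
        t1 = run_simulation(init, ff_ambient, protocol)
        t2 = run_simulation(init, ff_ambient, protocol)
        assert t1.n_frames == t2.n_frames == 4
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1.positions, f2.positions)

    def test_zero_production_leaves_single_snapshot(self, ff_ambient,
                                                    water_box_factory):
        protocol = Protocol(pre_thermalization_steps=100,
                            thermalization_steps=100, production_steps=0,
                            snapshot_interval=100, seed=5)
        init, _ = water_box_factory(60, seed=5)
        traj = run_simulation(init, ff_ambient, protocol)
        assert traj.n_frames == 1
        assert traj.frames[0].step == 200


class TestForceEquivalence:
    @pytest.mark.parametrize("n_beads", [60, 250])
    def test_cell_forces_match_all_pairs_oracle(self, ff_ambient, n_beads):
        rng = np.random.default_rng(n_beads)
        box = (n_beads / 3.0) ** (1 / 3)
        init = InitialConfiguration(
            box_side=box, positions=rng.uniform(0, box, (n_beads, 3)),
            types=rng.integers(0, 2, n_beads).astype(np.int64),
            bonds=np.array([[0, 1], [2, 3]]), n_polymer=0, n_water=n_beads)
        st = state_from_configuration(init, ff_ambient, seed=9)
        kb, r0 = 57.0, 0.85
        f = compute_forces(st, ff_ambient, init.bonds, (kb, r0),
                           include_random=False)
        # independent all-pairs oracle
        fm = ff_ambient.fmax_matrix()
        ref = np.zeros_like(f)
        for i in range(n_beads - 1):
            d = st.positions[i] - st.positions[i + 1:]
            d -= box * np.rint(d / box)
            r2 = (d * d).sum(axis=1)
            for jj in np.nonzero(r2 < 1.0)[0]:
                j = i + 1 + jj
                r = np.sqrt(r2[jj])
                e = d[jj] / r
                fc = fm[st.types[i], st.types[j]] * (1 - r)
                fd = -ff_ambient.gamma * np.dot(
                    e, st.velocities[i] - st.velocities[j])
                ref[i] += (fc + fd) * e
                ref[j] -= (fc + fd) * e
        for a, b in init.bonds:
            d = st.positions[a] - st.positions[b]
            d -= box * np.rint(d / box)
            r = np.linalg.norm(d)
            fb = -kb * (r - r0) / r
            ref[a] += fb * d
            ref[b] -= fb * d
        assert np.abs(f - ref).max() < 1e-10


class TestNeighborSearch:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        box = 5.0
        pos = rng.uniform(0, box, (200, 3))
        got = neighbor_search(pos, 1.0, box)
        ref = set()
        for i in range(199):
            d = pos[i + 1:] - pos[i]
            d -= box * np.rint(d / box)
            for j in np.nonzero((d * d).sum(axis=1) < 1.0)[0]:
                ref.add((i, int(j) + i + 1))
        assert got == ref

    def test_periodic_straddling_pair(self):
        pos = np.array([[0.1, 2.0, 2.0], [4.8, 2.0, 2.0]])  # 0.5 apart
        assert neighbor_search(pos, 1.0, 5.0) == {(0, 1)}

    def test_empty_box(self):
        assert neighbor_search(np.empty((0, 3)), 1.0, 5.0) == set()

    def test_cutoff_exceeding_half_box_rejected(self):
        with pytest.raises(GeometryError):
            neighbor_search(np.zeros((2, 3)), 3.0, 5.0)


class TestInstantaneousTemperature:
    def _state(self, vel, masses=None):
        n = len(vel)
        if masses is None:
            masses = np.ones(n)
        return SimulationState(
            positions=np.zeros((n, 3)), velocities=np.asarray(vel, float),
            images=np.zeros((n, 3), dtype=np.int64),
            types=np.zeros(n, dtype=np.int64), masses=masses, box_side=10.0)

    def test_zero_velocities(self):
        assert instantaneous_temperature(self._state(np.zeros((5, 3)))) == 0.0

    def test_equipartition_at_unit_temperature(self):
        v = maxwell_boltzmann_velocities(np.ones(10_000), seed=1)
        assert instantaneous_temperature(self._state(v)) == \
            pytest.approx(1.0, abs=0.02)

    def test_invariant_under_uniform_translation(self):
        v = maxwell_boltzmann_velocities(np.ones(500), seed=2)
        t0 = instantaneous_temperature(self._state(v))
        t1 = instantaneous_temperature(self._state(v + np.array([3.0, -1, 2])))
        assert t1 == pytest.approx(t0, rel=1e-10)
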