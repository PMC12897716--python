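"""Observable estimators: Rg, blocking SEM, RDFs, swelling, transition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpdgel.analysis import (
    block_sem, first_peak_position, max_diameter, radius_of_gyration,
    rdf_from_point, rdf_pair, swelling_ratio, transition_temperature,
)
from dpdgel.errors import (CoordinateError, DomainError,
                           InsufficientDataError)
from dpdgel.trajectory import Trajectory

# Published mean radii of gyration (angstrom) per simulated temperature.
TABLE1_DPD = {280: 44.00, 290: 42.45, 295: 39.89, 300: 37.59, 305: 33.15,
              310: 26.13, 315: 22.37, 320: 20.88, 330: 19.98}
TABLE1_LANGEVIN = {280: 48.87, 290: 47.79, 295: 46.20, 300: 43.30,
                   305: 37.75, 310: 31.43, 315: 28.41, 320: 27.38,
                   330: 26.78}


def _uniform_traj(n=5000, box=None, frames=4, seed=0, types=None):
    rng = np.random.default_rng(seed)
    if box is None:
        box = (n / 3.0) ** (1 / 3)
    traj = Trajectory()
    if types is None:
        types = np.zeros(n, dtype=np.int64)
    for k in range(frames):
        traj.append(k, box, rng.uniform(0, box, (n, 3)), types)
    return traj


class TestRadiusOfGyration:
    def test_two_beads(self):
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert radius_of_gyration(pos) == pytest.approx(1.5)

    def test_cube_corners(self):
        a = 2.0
        corners = np.array([[x, y, z] for x in (0, a) for y in (0, a)
                            for z in (0, a)])
        assert radius_of_gyration(corners) == pytest.approx(a * np.sqrt(3) / 2)

    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=25, derandomize=True)
    def test_translation_invariance(self, tx, ty, tz):
        rng = np.random.default_rng(7)
        pos = rng.normal(size=(20, 3))
        shifted = pos + np.array([tx, ty, tz])
        assert radius_of_gyration(shifted) == pytest.approx(
            radius_of_gyration(pos), rel=1e-9, abs=1e-9)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(8)
        pos = rng.normal(size=(30, 3))
        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).apply(pos)
        assert radius_of_gyration(rot) == pytest.approx(
            radius_of_gyration(pos), rel=1e-12)

    def test_wrapped_input_detected(self):
        pos = np.array([[0.1, 0, 0], [9.9, 0, 0]])
        bonds = np.array([[0, 1]])
        with pytest.raises(CoordinateError):
            radius_of_gyration(pos, box_side=10.0, bonds=bonds)

    def test_single_bead_rejected(self):
        with pytest.raises(DomainError):
            radius_of_gyration(np.zeros((1, 3)))


class TestBlockSem:
    def test_iid_recovers_root_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1024)
        mean, sem = block_sem(x)
        assert mean == pytest.approx(x.mean())
        assert sem == pytest.approx(1.0 / np.sqrt(1024), rel=0.25)

    def test_constant_series(self):
        _, sem = block_sem(np.full(200, 3.7))
        assert sem == pytest.approx(0.0, abs=1e-12)

    def test_ar1_exceeds_naive_estimate(self):
        # AR(1) x_t = phi x_{t-1} + e_t: var of the mean inflated by
        # (1+phi)/(1-phi) relative to iid
        phi = 0.9
        rng = np.random.default_rng(1)
        n = 20_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        sigma = np.sqrt(1.0 / (1 - phi**2))
        naive = sigma / np.sqrt(n)
        truth = sigma * np.sqrt((1 + phi) / ((1 - phi) * n))
        _, sem = block_sem(x)
        assert sem > 1.5 * naive
        assert sem == pytest.approx(truth, rel=0.3)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            block_sem(np.arange(30))


class TestRdfPair:
    def test_uniform_gas_is_flat(self):
        traj = _uniform_traj(n=5000, frames=30)
        idx = np.arange(5000)
        r, g = rdf_pair(traj, idx, idx, bin_width=0.1, r_max=5.0)
        assert np.all(np.abs(g - 1.0) < 0.05)

    def test_two_fixed_beads_single_bin(self):
        traj = Trajectory()
        pos = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 3.5]])
        traj.append(0, 10.0, pos, np.zeros(2, dtype=np.int64))
        r, g = rdf_pair(traj, [0], [1], bin_width=0.1, r_max=5.0)
        occupied = np.nonzero(g)[0]
        assert len(occupied) == 1
        assert r[occupied[0]] == pytest.approx(2.5, abs=0.05)

    def test_pair_count_closure(self):
        # rho_b * integral g 4 pi r^2 dr = mean neighbour count within r_max
        traj = _uniform_traj(n=2000, frames=2, seed=3)
        box = traj.frames[0].box_side
        idx = np.arange(2000)
        r_max = 3.0
        r, g = rdf_pair(traj, idx, idx, bin_width=0.05, r_max=r_max)
        edges = np.arange(0.0, r_max + 0.05, 0.05)[:len(g) + 1]
        shells = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        integral = ((2000 - 1) / box**3) * np.sum(g * shells)
        # direct count oracle
        from scipy.spatial import cKDTree
        direct = []
        for f in traj.frames:
            t = cKDTree(np.mod(f.positions, box), boxsize=box)
            direct.append(2 * len(t.query_pairs(r_max)) / 2000)
        assert integral == pytest.approx(np.mean(direct), rel=1e-6)

    def test_bad_parameters_rejected(self):
        traj = _uniform_traj(n=100, frames=1)
        with pytest.raises(DomainError):
            rdf_pair(traj, [0], [1], bin_width=0.0)
        with pytest.raises(DomainError):
            rdf_pair(traj, [0], [1], bin_width=0.1,
                     r_max=traj.frames[0].box_side)


class TestRdfFromPoint:
    def test_uniform_gas_is_flat(self):
        types = np.concatenate([np.ones(4, dtype=np.int64),
                                np.zeros(4000, dtype=np.int64)])
        traj = _uniform_traj(n=4004, frames=6, seed=2, types=types)
        water = np.arange(4, 4004)
        r, g = rdf_from_point(traj, water, bin_width=0.2, r_max=4.0)
        assert np.all(np.abs(g[2:] - 1.0) < 0.25)  # first bins: few counts
        assert np.abs(g[5:].mean() - 1.0) < 0.03

    def test_exclusion_sphere(self):
        rng = np.random.default_rng(5)
        box = 12.0
        center = np.full(3, box / 2)
        pts = rng.uniform(0, box, (30_000, 3))
        pts = pts[np.linalg.norm(pts - center, axis=1) > 2.0][:8000]
        types = np.concatenate([np.ones(2, dtype=np.int64),
                                np.zeros(len(pts), dtype=np.int64)])
        traj = Trajectory()
        poly = np.stack([center, center + 0.01])
        traj.append(0, box, np.vstack([poly, pts]), types)
        r, g = rdf_from_point(traj, np.arange(2, 2 + len(pts)),
                              bin_width=0.25, r_max=5.0)
        assert np.all(g[r < 1.9] < 1e-9)
        assert g[r > 2.5].mean() == pytest.approx(1.0, abs=0.1)


class TestSwellingRatio:
    def test_reference_is_unity(self):
        sw = swelling_ratio(TABLE1_DPD)
        assert sw[280] == 1.0

    def test_published_collapse_ratio(self):
        sw = swelling_ratio(TABLE1_DPD)
        assert sw[330] == pytest.approx(19.98 / 44.00, rel=1e-12)

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            swelling_ratio(TABLE1_DPD, T_ref=285)


class TestFirstPeak:
    def _gaussian_bump(self, center, bins=None):
        r = np.arange(0.05, 12.0, 0.1) if bins is None else bins
        g = 1.0 + 2.0 * np.exp(-((r - center) / 0.5) ** 2)
        return r, g

    @pytest.mark.parametrize("center", [6.5, 6.8, 6.75])
    def test_recovers_bump_position(self, center):
        r, g = self._gaussian_bump(center)
        assert first_peak_position(r, g) == pytest.approx(center, abs=0.05)

    def test_monotone_curve_has_no_peak(self):
        r = np.arange(0.05, 5.0, 0.1)
        assert first_peak_position(r, np.exp(-r)) is None

    def test_needs_three_bins(self):
        with pytest.raises(DomainError):
            first_peak_position(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestTransitionTemperature:
    def test_published_dpd_bracket(self):
        assert transition_temperature(TABLE1_DPD) == (305.0, 310.0)

    def test_published_langevin_bracket(self):
        assert transition_temperature(TABLE1_LANGEVIN) == (305.0, 310.0)

    def test_linear_profile_degenerate(self):
        rg = {T: 100.0 - 0.5 * T for T in (280, 290, 300, 310)}
        assert transition_temperature(rg) is None

    def test_monotone_flat_no_transition(self):
        rg = {280: 40.0, 290: 40.0, 300: 40.0, 310: 40.0}
        assert transition_temperature(rg) is None
        rg_up = {280: 40.0, 290: 41.0, 300: 43.0, 310: 46.0}
        assert transition_temperature(rg_up) is None

    def test_too_few_temperatures_rejected(self):
        with pytest.raises(DomainError):
            transition_temperature({280: 44.0, 330: 20.0})


class TestMaxDiameter:
    def test_tail_threshold(self):
        r = np.arange(0.1, 10.0, 0.1)
        g = np.where(r < 6.0, 2.0, 0.0)
        assert max_diameter(r, g) == pytest.approx(5.9, abs=0.11)
        assert max_diameter(r, np.zeros_like(r)) is None
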