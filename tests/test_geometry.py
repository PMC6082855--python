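"""Distance-space analyses: oracles, ultrametricity, planted scalings, droplets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccmpoly.core import LoopSet
from ccmpoly.geometry import (
    contact_distance_exponent,
    detect_droplets,
    droplet_growth,
    gyration_shape,
    hic_to_distance,
    mean_distance_map,
    r_of_s,
    tad_shape_stats,
    ward_linkage_matrix,
    wlm_similarity,
    wlm_similarity_population,
)
from ccmpoly.trajectory import Trajectory


def static_traj(pos):
    return Trajectory(frames=np.asarray(pos)[None], times=np.array([0.0]))


class TestMeanDistanceMap:
    def test_static_equals_instantaneous(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 5, (12, 3))
        r = mean_distance_map(static_traj(pos))
        from scipy.spatial.distance import pdist, squareform

        assert np.allclose(r, squareform(pdist(pos)))

    def test_two_frame_hand_average(self):
        f0 = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        f1 = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        traj = Trajectory(frames=np.stack([f0, f1]), times=np.array([0.0, 1.0]))
        r = mean_distance_map(traj)
        assert r[0, 1] == pytest.approx(2.0)

    def test_ensemble_of_identical_equals_single(self):
        pos = np.random.default_rng(1).uniform(0, 3, (8, 3))
        t = static_traj(pos)
        r1 = mean_distance_map(t, mode="single_cell")
        r2 = mean_distance_map([t, t, t], mode="ensemble")
        assert np.allclose(r1, r2)


class TestRofS:
    def test_rod_closed_form(self):
        b = 1.3
        pos = np.zeros((20, 3))
        pos[:, 0] = b * np.arange(20)
        s, r, dr = r_of_s(static_traj(pos))
        assert np.allclose(r, b * s)
        assert np.allclose(dr, 0.0, atol=1e-6)

    def test_frozen_structure_has_no_time_contribution(self):
        # repeating a frame adds nothing to the distance-population spread
        pos = np.random.default_rng(2).uniform(0, 4, (15, 3))
        one = static_traj(pos)
        two = Trajectory(frames=np.stack([pos, pos]), times=np.array([0.0, 1.0]))
        _, r1, d1 = r_of_s(one)
        _, r2, d2 = r_of_s(two)
        assert np.allclose(r1, r2)
        assert np.allclose(d1, d2)

    def test_gaussian_chain_exponent(self):
        rng = np.random.default_rng(3)
        frames = np.cumsum(rng.standard_normal((200, 120, 3)) / np.sqrt(3), axis=1)
        traj = Trajectory(frames=frames, times=np.arange(200.0))
        s, r, _ = r_of_s(traj)
        from ccmpoly.contacts import fit_power_law

        expo, _ = fit_power_law(s, r, (2, 40))
        assert expo == pytest.approx(0.5, abs=0.02)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        frames = rng.uniform(0, 3, (4, 25, 3))
        traj = Trajectory(frames=frames, times=np.arange(4.0))
        s, r, dr = r_of_s(traj)
        for sv in (1, 7, 20):
            vals = []
            for f in frames:
                for i in range(25 - sv):
                    vals.append(np.linalg.norm(f[i] - f[i + sv]))
            vals = np.array(vals)
            assert r[sv - 1] == pytest.approx(np.sqrt(np.mean(vals**2)), rel=1e-12)
            assert dr[sv - 1] == pytest.approx(vals.std() / vals.mean(), rel=1e-9)


class TestWardLinkage:
    def test_three_point_hand_agglomeration(self):
        # points on a line: tight pair (0,1) at distance 1; point 2 at 10
        d = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 9.0], [10.0, 9.0, 0.0]])
        w = ward_linkage_matrix(d)
        assert w[0, 1] < w[0, 2]
        assert w[0, 1] < w[1, 2]
        assert w[0, 1] == pytest.approx(1.0)  # first merge at its distance

    def test_identical_points_zero_matrix(self):
        w = ward_linkage_matrix(np.zeros((6, 6)))
        assert np.all(w == 0.0)

    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 5, (20, 3))
        from scipy.spatial.distance import pdist, squareform

        w = ward_linkage_matrix(squareform(pdist(pts)))
        assert wlm_similarity(w, w) == pytest.approx(1.0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_ultrametric_inequality(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (12, 3))
        from scipy.spatial.distance import pdist, squareform

        w = ward_linkage_matrix(squareform(pdist(pts)))
        n = w.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert w[i, k] <= max(w[i, j], w[j, k]) + 1e-9

    def test_affine_rescaled_similarity_one(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 5, (15, 3))
        from scipy.spatial.distance import pdist, squareform

        w = ward_linkage_matrix(squareform(pdist(pts)))
        assert wlm_similarity(w, 3.0 * w + 2.0) == pytest.approx(1.0)

    def test_population_null_is_small(self):
        rng = np.random.default_rng(7)
        wlms = []
        for _ in range(8):
            pts = rng.uniform(0, 5, (30, 3))
            from scipy.spatial.distance import pdist, squareform

            wlms.append(ward_linkage_matrix(squareform(pdist(pts))))
        rhos, rho_bar = wlm_similarity_population(wlms)
        assert len(rhos) == 28
        assert abs(rho_bar) < 0.5  # unrelated structures share little


class TestHicToDistance:
    def test_homogeneity(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.1, 1.0, (10, 10))
        p = (p + p.T) / 2
        r1 = hic_to_distance(p)
        r2 = hic_to_distance(2 * p)
        off = ~np.eye(10, dtype=bool)
        assert np.allclose(r2[off] / r1[off], 2 ** (-1 / 4.1))

    def test_sixteen_fold_ratio(self):
        p = np.array([[0.0, 16.0, 1.0], [16.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        r = hic_to_distance(p, exponent=4.1)
        assert r[0, 1] / r[0, 2] == pytest.approx(16 ** (-1 / 4.1))

    def test_zero_floored_with_warning(self):
        p = np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 0.25], [0.0, 0.25, 0.0]])
        with pytest.warns(UserWarning):
            r = hic_to_distance(p)
        assert np.all(np.isfinite(r))


class TestContactDistanceExponent:
    def _planted(self, lam, n=80, seed=9):
        rng = np.random.default_rng(seed)
        r = rng.uniform(1.0, 20.0, (n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        with np.errstate(divide="ignore"):
            c = r ** (-lam)
        np.fill_diagonal(c, 0)
        return c, r

    @pytest.mark.parametrize("lam", [4.0, 3.0])
    def test_planted_exponent(self, lam):
        c, r = self._planted(lam)
        est, _ = contact_distance_exponent(c, r)
        assert est == pytest.approx(lam, abs=1e-6)

    def test_constant_counts_zero_slope(self):
        c, r = self._planted(4.0)
        c = np.ones_like(c)
        np.fill_diagonal(c, 0)
        est, _ = contact_distance_exponent(c, r)
        assert est == pytest.approx(0.0, abs=1e-9)


class TestGyrationShape:
    def test_rod_limit(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        rg, kappa2, s = gyration_shape(pts)
        assert kappa2 == pytest.approx(1.0)
        assert s == pytest.approx(2.0)

    def test_octahedron_isotropic(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        rg, kappa2, s = gyration_shape(pts)
        assert kappa2 == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_four_point_hand_computed_tensor(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 1.0, 0], [2.0, 1.0, 1.0]])
        c = pts - pts.mean(axis=0)
        lam = np.sort(np.linalg.eigvalsh(c.T @ c / 4))[::-1]
        rg, kappa2, s = gyration_shape(pts)
        tr = lam.sum()
        assert rg == pytest.approx(np.sqrt(tr))
        expect_k2 = 1 - 3 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / tr**2
        assert kappa2 == pytest.approx(expect_k2, rel=1e-12)
        mbar = tr / 3
        assert s == pytest.approx(27 * np.prod(lam - mbar) / tr**3, rel=1e-12)

    def test_shape_bounds(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            pts = rng.standard_normal((8, 3))
            _, kappa2, s = gyration_shape(pts)
            assert -1e-9 <= kappa2 <= 1 + 1e-9
            assert -0.25 - 1e-9 <= s <= 2 + 1e-9


class TestTadShapes:
    def test_identical_trajectories_mass_at_one(self):
        rng = np.random.default_rng(11)
        frames = rng.uniform(0, 5, (3, 30, 3))
        traj = Trajectory(frames=frames, times=np.arange(3.0))
        loops = LoopSet(np.array([[2, 10], [15, 25]]))
        stats = tad_shape_stats([traj, traj, traj], loops)
        assert np.allclose(stats.rg2_norm, 1.0)
        assert np.allclose(stats.s_norm, 1.0)

    def test_two_state_mixture_bimodal(self):
        rng = np.random.default_rng(12)
        compact = 0.3 * rng.standard_normal((4, 20, 3))
        extended = np.zeros((4, 20, 3))
        extended[:, :, 0] = np.arange(20)
        extended += 0.1 * rng.standard_normal((4, 20, 3))
        loops = LoopSet(np.array([[0, 19]]))
        trajs = [
            Trajectory(frames=compact, times=np.arange(4.0)),
            Trajectory(frames=extended, times=np.arange(4.0)),
        ]
        stats = tad_shape_stats(trajs, loops)
        vals = stats.rg2_norm[0]
        assert vals.max() / vals.min() > 5  # clearly separated populations


class TestDroplets:
    def _blob(self, center, n, seed):
        rng = np.random.default_rng(seed)
        return center + 0.6 * rng.standard_normal((n, 3))

    def test_two_separated_blobs(self):
        pos = np.vstack([self._blob([0, 0, 0], 25, 1), self._blob([20, 0, 0], 25, 2)])
        clusters = detect_droplets(pos, linkage_radius=2.0, min_size=10)
        assert len(clusters) == 2
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [25, 25]

    def test_single_globule_contains_all(self):
        pos = self._blob([0, 0, 0], 60, 3)
        clusters = detect_droplets(pos, linkage_radius=2.0, min_size=10)
        assert len(clusters) == 1
        assert len(clusters[0]) == 60

    def test_planted_coalescence_schedule(self):
        # four blobs of 20 beads merge pairwise over three frames
        rng = np.random.default_rng(4)
        def blobs(centers):
            return np.vstack([c + 0.5 * rng.standard_normal((20, 3)) for c in centers])

        f0 = blobs([[0, 0, 0], [30, 0, 0], [60, 0, 0], [90, 0, 0]])
        f1 = blobs([[0, 0, 0], [1.0, 0, 0], [60, 0, 0], [90, 0, 0]])
        f2 = blobs([[0, 0, 0], [1.0, 0, 0], [60, 0, 0], [61.0, 0, 0]])
        traj = Trajectory(frames=np.stack([f0, f1, f2]), times=np.arange(1.0, 4.0))
        trace = droplet_growth(traj, bead_bp=1200, linkage_radius=2.0, min_size=10)
        assert trace.n_bp[0] == pytest.approx(20 * 1200)
        assert trace.n_bp[1] == pytest.approx(np.mean([40, 20, 20]) * 1200)
        assert trace.n_bp[2] == pytest.approx(40 * 1200)

    def test_no_droplets_recorded_missing(self):
        pos = np.arange(30.0)[:, None] * np.array([5.0, 0, 0])  # isolated beads
        traj = Trajectory(frames=pos[None], times=np.array([1.0]))
        trace = droplet_growth(traj)
        assert np.isnan(trace.n_bp[0])


class TestCollapsedGlobuleDistanceProperties:
    """Distance-space properties on collapsed-copolymer ensembles."""

    def test_delta_r_rises_then_falls(self, glass_sampling_traj):
        # structural variability peaks at an intermediate genomic scale
        _, _, _, traj = glass_sampling_traj
        s, r, dr = r_of_s(traj)
        smooth = np.convolve(dr, np.ones(9) / 9, mode="valid")
        peak = smooth.max()
        assert peak > smooth[0] * 1.1   # rises from short separations
        assert peak > smooth[-1] * 1.1  # and falls toward the chain scale

    def test_single_cell_wlm_heterogeneity(self, glass_relax_ensemble):
        # individual cells fold differently (rho-bar << 1) while disjoint
        # half-ensemble averages still agree better than single cells do
        _, _, trajs = glass_relax_ensemble
        wlms = [ward_linkage_matrix(mean_distance_map(t)) for t in trajs]
        rhos, rho_bar = wlm_similarity_population(wlms)
        assert rho_bar < 0.6
        half_a = ward_linkage_matrix(
            mean_distance_map(trajs[:2], mode="ensemble"))
        half_b = ward_linkage_matrix(
            mean_distance_map(trajs[2:], mode="ensemble"))
        assert wlm_similarity(half_a, half_b) > rho_bar
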