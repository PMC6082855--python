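"""Contact-map statistics: brute-force oracles, planted models, null calibrations."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from ccmpoly.contacts import (
    ContactStats,
    ami,
    call_tads,
    compartments_cocluster,
    contact_map,
    contact_probability,
    crossover_scale,
    directionality_index,
    fit_power_law,
    log_binned_ps,
    radial_density_profile,
    radial_distribution,
    spearman_map,
    subchain_contacts,
)
from ccmpoly.core import CCMParameters, EpigenomeAnnotation
from ccmpoly.trajectory import Trajectory


def rod_trajectory(n=8, spacing=1.0):
    pos = np.zeros((n, 3))
    pos[:, 0] = spacing * np.arange(n)
    return Trajectory(frames=pos[None], times=np.array([0.0]))


class TestContactMap:
    def test_rod_band_structure(self):
        params = CCMParameters(n_beads=8, r_contact=2.0)
        stats = contact_map(rod_trajectory(8), params)
        for i in range(8):
            for j in range(8):
                expected = 1.0 if 0 < abs(i - j) <= 1 else 0.0
                assert stats.counts[i, j] == expected

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 4, size=(7, 30, 3))
        traj = Trajectory(frames=frames, times=np.arange(7.0))
        params = CCMParameters(n_beads=30, r_contact=1.5)
        stats = contact_map(traj, params)
        brute = np.zeros((30, 30))
        for f in frames:
            d = squareform(pdist(f))
            for i in range(30):
                for j in range(30):
                    if i != j and d[i, j] < 1.5:
                        brute[i, j] += 1
        assert np.array_equal(stats.counts, brute)

    def test_vanishing_threshold_gives_zero_matrix(self):
        params = CCMParameters(n_beads=8, r_contact=1e-9)
        stats = contact_map(rod_trajectory(8), params)
        assert stats.counts.sum() == 0

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(frames=np.empty((0, 5, 3)), times=np.empty(0))


class TestContactProbability:
    def test_rod_ps(self):
        params = CCMParameters(n_beads=8, r_contact=2.0)
        s, ps = contact_probability(contact_map(rod_trajectory(8), params))
        assert ps[0] == 1.0       # s = 1
        assert np.all(ps[2:] == 0.0)

    def test_all_ones_matrix(self):
        m = np.ones((10, 10))
        np.fill_diagonal(m, 0)
        stats = ContactStats(counts=m, n_frames=1)
        _, ps = contact_probability(stats)
        assert np.allclose(ps, 1.0)

    def test_planted_power_law_recovered(self):
        n = 60
        idx = np.arange(n)
        m = 1.0 / np.maximum(np.abs(idx[:, None] - idx[None, :]), 1) ** 1.0
        np.fill_diagonal(m, 0)
        stats = ContactStats(counts=m, n_frames=1)
        s, ps = contact_probability(stats)
        expo, _ = fit_power_law(s, ps, (1, 30))
        assert expo == pytest.approx(-1.0, abs=1e-10)

    def test_log_binning_preserves_planted_slope(self):
        s = np.arange(1, 500)
        ps = s ** (-0.8)
        sb, pb = log_binned_ps(s, ps)
        expo, _ = fit_power_law(sb, pb)
        assert expo == pytest.approx(-0.8, abs=0.02)


class TestFitPowerLaw:
    @pytest.mark.parametrize("expo", [-0.75, 0.0, 1.0, -1.25])
    def test_exact_on_noiseless_laws(self, expo):
        x = np.linspace(1, 100, 200)
        y = 3.0 * x**expo
        slope, err = fit_power_law(x, y)
        assert slope == pytest.approx(expo, abs=1e-12)

    def test_noisy_within_two_stderr(self):
        rng = np.random.default_rng(5)
        x = np.linspace(1, 100, 200)
        y = x**-0.6 * np.exp(rng.normal(0, 0.1, size=200))
        slope, err = fit_power_law(x, y)
        assert abs(slope + 0.6) < 2 * err + 1e-12

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([1.0]), np.array([2.0]))


class TestCrossover:
    def test_planted_breakpoint_recovered(self):
        s = np.unique(np.geomspace(1, 4000, 120).astype(int)).astype(float)
        break_at = 400.0
        amp = break_at ** (-0.75 + 1.25)
        ps = np.where(s < break_at, s**-0.75, amp * s**-1.25)
        fit = crossover_scale(s, ps)
        assert not fit.no_crossover
        assert fit.slope_small == pytest.approx(-0.75, abs=0.02)
        assert fit.slope_large == pytest.approx(-1.25, abs=0.02)
        # within one log-bin of the planted break
        assert abs(np.log(fit.s_star / break_at)) < 0.15

    def test_single_power_law_flagged(self):
        s = np.geomspace(1, 1000, 80)
        fit = crossover_scale(s, s**-1.0)
        assert fit.no_crossover

    def test_bp_conversion(self):
        s = np.unique(np.geomspace(1, 4000, 120).astype(int)).astype(float)
        ps = np.where(s < 300, s**-0.7, 300**0.6 * s**-1.3)
        fit = crossover_scale(s, ps, CCMParameters(n_beads=5000))
        assert fit.s_star_bp == pytest.approx(fit.s_star * 1200)


class TestSubchainContacts:
    def test_zero_matrix(self):
        stats = ContactStats(counts=np.zeros((20, 20)), n_frames=1)
        assert np.all(subchain_contacts(stats, [1, 5, 10]) == 0.0)

    def test_all_ones_closed_form(self):
        n = 12
        m = np.ones((n, n))
        np.fill_diagonal(m, 0)
        stats = ContactStats(counts=m, n_frames=1)
        for s in (1, 3, 6):
            a = subchain_contacts(stats, [s])[0]
            assert a == pytest.approx(s * (n - s))  # every window identical

    def test_invalid_s(self):
        stats = ContactStats(counts=np.zeros((5, 5)), n_frames=1)
        with pytest.raises(ValueError):
            subchain_contacts(stats, [5])


def checkerboard(n, block, high=2.0, low=1.0, noise=0.0, seed=0):
    labels = (np.arange(n) // block) % 2
    m = np.where(labels[:, None] == labels[None, :], high, low).astype(float)
    if noise:
        rng = np.random.default_rng(seed)
        sym = rng.normal(0, noise, (n, n))
        m += sym + sym.T
    np.fill_diagonal(m, 0)
    return m, labels


class TestSpearmanAndCompartments:
    def test_identical_and_antiranked_rows(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        m = np.vstack([base] * 6)
        m = (m + m.T) / 2  # symmetrize keeps rows correlated
        sp = spearman_map(m, exclude_band=0)
        assert np.all(sp >= -1 - 1e-12)
        assert sp[0, 1] > 0.9

    def test_checkerboard_within_vs_between(self):
        m, labels = checkerboard(40, 10)
        sp = spearman_map(m)
        within = [sp[i, j] for i in range(40) for j in range(40)
                  if i < j and labels[i] == labels[j]]
        between = [sp[i, j] for i in range(40) for j in range(40)
                   if i < j and labels[i] != labels[j]]
        assert np.mean(within) > np.mean(between)

    def test_cocluster_exact_recovery_at_two_to_one_contrast(self):
        m, labels = checkerboard(500, 50, high=2.0, low=1.0, noise=0.05)
        sp = spearman_map(m)
        res = compartments_cocluster(sp, seed=0)
        assert ami(res.labels, labels) == pytest.approx(1.0)

    def test_constant_matrix_degenerate(self):
        res = compartments_cocluster(np.zeros((20, 20)))
        assert res.degenerate

    def test_permuted_labels_same_partition(self):
        m, labels = checkerboard(100, 25)
        sp = spearman_map(m)
        a = compartments_cocluster(sp, seed=0).labels
        b = compartments_cocluster(sp, seed=5).labels
        assert ami(a, b) == pytest.approx(1.0)


class TestAmi:
    def test_identical_and_permuted(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert ami(labels, labels) == pytest.approx(1.0)
        assert ami(labels, 2 - labels) == pytest.approx(1.0)

    def test_independent_random_null(self):
        rng = np.random.default_rng(0)
        scores = [
            ami(rng.integers(0, 2, 1000), rng.integers(0, 2, 1000))
            for _ in range(100)
        ]
        assert abs(np.mean(scores)) < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ami([0, 1], [0, 1, 2])


class TestDirectionalityIndex:
    def test_uniform_matrix_zero_di(self):
        m = np.ones((40, 40))
        np.fill_diagonal(m, 0)
        di = directionality_index(m, window=8)
        interior = di[8:-8]
        assert np.allclose(interior, 0.0)
        assert call_tads(di, window=8) == []

    def test_single_block_sign_structure(self):
        m = np.zeros((60, 60))
        m[20:40, 20:40] = 5.0
        np.fill_diagonal(m, 0)
        di = directionality_index(m, window=10)
        assert di[20] > 0  # block start: downstream bias
        assert di[39] < 0  # block end: upstream bias

    def test_two_planted_blocks_recovered(self):
        m = np.full((80, 80), 0.05)
        m[10:30, 10:30] = 5.0
        m[45:70, 45:70] = 5.0
        np.fill_diagonal(m, 0)
        di = directionality_index(m, window=8)
        tads = call_tads(di, window=8)
        assert len(tads) == 2
        (a0, a1), (b0, b1) = tads
        assert abs(a0 - 10) <= 1 and abs(a1 - 30) <= 1
        assert abs(b0 - 45) <= 1 and abs(b1 - 70) <= 1

    def test_window_bound(self):
        with pytest.raises(ValueError):
            directionality_index(np.zeros((10, 10)), window=5)


class TestRadialStats:
    def _uniform_sphere(self, n, radius, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4 * n, 3))
        pts *= radius * rng.random(4 * n)[:, None] ** (1 / 3) / np.linalg.norm(
            pts, axis=1, keepdims=True
        )
        return pts[:n]

    def test_ideal_gas_g_of_r_near_one(self):
        pts = self._uniform_sphere(3000, 10.0, 1)
        traj = Trajectory(frames=pts[None], times=np.array([0.0]))
        ann = EpigenomeAnnotation(labels=np.full(3000, "A"))
        r, g, _ = radial_distribution(traj, ann, "AA", r_max=10.0, dr=0.5)
        core = (r > 1.0) & (r < 4.0)  # away from boundary shells
        assert np.allclose(g[core], 1.0, atol=0.15)

    def test_two_point_peak(self):
        pts = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        traj = Trajectory(frames=pts[None], times=np.array([0.0]))
        ann = EpigenomeAnnotation(labels=np.array(["A", "B"]))
        r, g, _ = radial_distribution(traj, ann, "AB", r_max=5.0, dr=0.2)
        assert r[np.argmax(g)] == pytest.approx(3.0, abs=0.21)

    def test_uniform_sphere_density_profile(self):
        pts = self._uniform_sphere(5000, 8.0, 2)
        pts -= pts.mean(axis=0)
        traj = Trajectory(frames=pts[None], times=np.array([0.0]))
        ann = EpigenomeAnnotation(labels=np.full(5000, "A"))
        prof = radial_density_profile(traj, ann, r_max=8.0, dr=1.0)
        inner = (prof["r"] > 1.5) & (prof["r"] < 6.0)
        assert np.allclose(prof["A"][inner], 1.0, atol=0.2)

    def test_origin_cluster_all_in_first_shells(self):
        pts = np.zeros((50, 3)) + 1e-6 * np.arange(50)[:, None]
        traj = Trajectory(frames=pts[None], times=np.array([0.0]))
        ann = EpigenomeAnnotation(labels=np.full(50, "B"))
        prof = radial_density_profile(traj, ann, r_max=2.0, dr=0.5)
        assert prof["B"][0] > 0
        assert np.all(prof["B"][1:] == 0)


class TestCollapsedGlobuleContactProperties:
    """Contact-space properties measured on a collapsed copolymer globule."""

    def test_subchain_contacts_compact_scaling(self, glass_sampling_traj):
        # compact structure: A(s) ~ s^(2/3); ideal chain would give ~ s^1
        params, _, _, traj = glass_sampling_traj
        stats = contact_map(traj, params)
        svals = np.unique(np.geomspace(4, params.n_beads // 4, 15).astype(int))
        a_s = subchain_contacts(stats, svals)
        slope, _ = fit_power_law(svals, a_s)
        assert slope == pytest.approx(2 / 3, abs=0.2)
        assert slope < 1.0

    def test_homopolymer_control_has_no_compartments(
        self, homopolymer_sampling_traj
    ):
        # eps_AB = eps removes the driving force for micro-phase separation:
        # co-clustered compartments are uncorrelated with the A/B annotation
        params, ann, traj = homopolymer_sampling_traj
        stats = contact_map(traj, params)
        sp = spearman_map(stats.probability)
        comp = compartments_cocluster(sp, seed=0)
        assert abs(ami(comp.labels, ann.types)) < 0.05

    def test_glass_globule_gr_ordering(self, glass_bd_ensemble, shared_system):
        ann, _ = shared_system
        _, _, trajs = glass_bd_ensemble
        r, gaa, r_s = radial_distribution(trajs[0], ann, "AA", min_sep=4)
        _, gbb, _ = radial_distribution(trajs[0], ann, "BB", min_sep=4)
        _, gab, _ = radial_distribution(trajs[0], ann, "AB", min_sep=4)
        i = np.argmin(np.abs(r - r_s))
        assert gaa[i] > gab[i] and gbb[i] > gab[i]
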