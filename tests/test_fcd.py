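import numpy as np
import pytest

from conftest import make_random_hub_config, make_two_block_bold
from oracles import gfcd_oracle, lfcd_oracle, masked_smooth_oracle

from neurofcd.fcd import (
    DensityMap,
    FcdConfig,
    LogFcdMap,
    compute_fcd_pair,
    compute_gfcd,
    compute_lfcd,
    log_fcd,
    long_range_map,
    pairwise_correlation,
    participant_fcd,
    smooth_log_fcd,
)
from neurofcd.io_volumes import BoldSeries, Mask, VolumeGrid
from neurofcd.synthetic import generate_bold


def constant_bold(shape=(3, 3, 3), n_t=40, seed=0):
    """All voxels share one series: the fully connected, fully contiguous case."""
    rng = np.random.default_rng(seed)
    series = rng.standard_normal(n_t)
    data = np.broadcast_to(series, shape + (n_t,)).copy()
    return BoldSeries(VolumeGrid(shape, (2.0, 2.0, 2.0)), data)


def noise_bold(shape=(6, 6, 6), n_t=120, seed=0):
    rng = np.random.default_rng(seed)
    return BoldSeries(VolumeGrid(shape, (2.0, 2.0, 2.0)),
                      rng.standard_normal(shape + (n_t,)))


def full_mask_for(bold):
    return Mask(bold.grid, np.ones(bold.grid.shape, dtype=bool))


class TestPairwiseCorrelation:
    def test_identical_series_give_one(self):
        b = constant_bold()
        assert pairwise_correlation(b, (0, 0, 0), (2, 2, 2)) == pytest.approx(1.0, abs=1e-12)

    def test_negated_series_give_minus_one(self):
        b = noise_bold((2, 1, 1), 30)
        b.data[1, 0, 0] = -b.data[0, 0, 0]
        assert pairwise_correlation(b, (0, 0, 0), (1, 0, 0)) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_value(self):
        grid = VolumeGrid((2, 1, 1), (2.0, 2.0, 2.0))
        data = np.zeros((2, 1, 1, 4))
        data[0, 0, 0] = [1, 2, 3, 4]
        data[1, 0, 0] = [1, 2, 3, 5]
        b = BoldSeries(grid, data)
        expected = 6.5 / np.sqrt(5.0 * 8.75)  # cov / (sd_x * sd_y), computed by hand
        assert pairwise_correlation(b, (0, 0, 0), (1, 0, 0)) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises(self):
        b = noise_bold((2, 1, 1), 30)
        b.data[0, 0, 0] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_correlation(b, (0, 0, 0), (1, 0, 0))


class TestFixtures:
    def test_fully_connected_cube(self):
        b = constant_bold((3, 3, 3))
        mask = full_mask_for(b)
        g, l = compute_fcd_pair(b, mask)
        assert np.all(g.counts == 26)
        assert np.all(l.counts == 26)
        lr = long_range_map(g, l)
        assert np.all(lr.counts == 0)

    def test_two_disjoint_blocks(self, two_block_bold, block_voxels):
        mask = full_mask_for(two_block_bold)
        g, l = compute_fcd_pair(two_block_bold, mask)
        lr = long_range_map(g, l)
        for v in block_voxels[0] + block_voxels[1]:
            assert l.counts[v] == 7  # own contiguous block only
            assert g.counts[v] == 15  # 7 own + 8 in the far block
            assert lr.counts[v] == 8
        # cross-checked against the independent brute-force oracles
        assert np.array_equal(g.counts, gfcd_oracle(two_block_bold, mask))
        assert np.array_equal(l.counts, lfcd_oracle(two_block_bold, mask))

    def test_line_of_five_with_face_connectivity(self):
        b = noise_bold((6, 6, 6), 80, seed=3)
        series = np.random.default_rng(99).standard_normal(80)
        for k in range(5):
            b.data[k, 2, 2] = series
        mask = full_mask_for(b)
        l = compute_lfcd(b, mask, FcdConfig(neighborhood=6))
        for k in range(5):
            assert l.counts[k, 2, 2] == 4

    def test_null_noise_has_no_edges(self):
        # white noise, n = 120: P(r > 0.6) is ~3e-13 per pair, so the 0.999
        # binomial quantile of the total edge count over all pairs is zero
        from scipy.stats import beta as beta_dist

        b = noise_bold((6, 6, 6), 120, seed=11)
        mask = full_mask_for(b)
        n = 120
        a = (n - 2) / 2.0
        p_edge = float(beta_dist.sf((0.6 + 1) / 2, a, a))
        n_pairs = 216 * 215 // 2
        assert n_pairs * p_edge < 1e-3  # quantile(0.999) == 0
        g = compute_gfcd(b, mask)
        assert g.counts.sum() == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bfs_and_pair_counting(self, seed):
        cfg = make_random_hub_config(seed)
        b = generate_bold(cfg, 0)
        mask = full_mask_for(b)
        go = gfcd_oracle(b, mask)
        for nb in (6, 18, 26):
            g, l = compute_fcd_pair(b, mask, FcdConfig(neighborhood=nb))
            assert np.array_equal(g.counts, go)
            assert np.array_equal(l.counts, lfcd_oracle(b, mask, neighborhood=nb))


class TestInvariants:
    def test_bounds_and_monotonicity(self):
        cfg = make_random_hub_config(17)
        b = generate_bold(cfg, 0)
        mask = full_mask_for(b)
        n = mask.n_voxels
        prev_g = prev_l = None
        for t in (0.4, 0.6, 0.8):
            g, l = compute_fcd_pair(b, mask, FcdConfig(correlation_threshold=t))
            assert np.all(l.counts <= g.counts)
            assert np.all(g.counts <= n - 1)
            assert np.all(l.counts >= 0)
            if prev_g is not None:  # raising the threshold never increases counts
                assert np.all(g.counts <= prev_g)
                assert np.all(l.counts <= prev_l)
            prev_g, prev_l = g.counts, l.counts

    def test_positive_affine_series_invariance(self):
        cfg = make_random_hub_config(23)
        b = generate_bold(cfg, 0)
        mask = full_mask_for(b)
        g0, l0 = compute_fcd_pair(b, mask)
        rng = np.random.default_rng(0)
        scale = rng.uniform(0.5, 3.0, b.grid.shape)[..., None]
        shift = rng.uniform(-5, 5, b.grid.shape)[..., None]
        b2 = BoldSeries(b.grid, b.data * scale + shift, b.sampling_interval_s)
        g1, l1 = compute_fcd_pair(b2, mask)
        assert np.array_equal(g0.counts, g1.counts)
        assert np.array_equal(l0.counts, l1.counts)

    def test_neighborhood_monotonicity(self):
        cfg = make_random_hub_config(31)
        b = generate_bold(cfg, 0)
        mask = full_mask_for(b)
        counts = {}
        g_by_nb = {}
        for nb in (6, 18, 26):
            g, l = compute_fcd_pair(b, mask, FcdConfig(neighborhood=nb))
            counts[nb] = l.counts
            g_by_nb[nb] = g.counts
        assert np.all(counts[6] <= counts[18])
        assert np.all(counts[18] <= counts[26])
        assert np.array_equal(g_by_nb[6], g_by_nb[26])  # gFCD ignores adjacency


class TestLongRange:
    def test_mismatched_masks_rejected(self):
        b = noise_bold(seed=2)
        m1 = full_mask_for(b)
        m2 = Mask(b.grid, np.ones(b.grid.shape, dtype=bool))
        m2.membership[0, 0, 0] = False
        g = compute_gfcd(b, m1)
        l = compute_lfcd(b, m2)
        with pytest.raises(ValueError, match="different masks|different runs"):
            long_range_map(g, l)

    def test_negative_difference_aborts(self):
        grid = VolumeGrid((2, 2, 2), (2.0, 2.0, 2.0))
        g = DensityMap(grid, np.full((2, 2, 2), 1.0), kind="gfcd")
        l = DensityMap(grid, np.full((2, 2, 2), 2.0), kind="lfcd")
        with pytest.raises(ValueError, match="inconsistent"):
            long_range_map(g, l)


class TestLogTransform:
    def grid_map(self, counts, kind="lfcd"):
        counts = np.asarray(counts, dtype=float)
        return DensityMap(VolumeGrid(counts.shape, (2.0, 2.0, 2.0)), counts, kind=kind)

    def test_values_and_zero_handling(self):
        d = self.grid_map(np.array([[[1.0, 26.0], [0.0, 3.0]]]).reshape(1, 2, 2))
        out = log_fcd(d)
        assert out.kind == "srfcd"
        assert out.values[0, 0, 0] == pytest.approx(0.0)
        assert out.values[0, 0, 1] == pytest.approx(np.log(26), abs=1e-12)
        assert np.isnan(out.values[0, 1, 0])  # zero count -> missing
        added = log_fcd(d, FcdConfig(zero_handling="add_one"))
        assert added.values[0, 1, 0] == pytest.approx(0.0)
        assert added.values[0, 0, 1] == pytest.approx(np.log(27))

    def test_long_range_becomes_lrfcd(self):
        out = log_fcd(self.grid_map(np.ones((1, 2, 2)), kind="long_range"))
        assert out.kind == "lrfcd"

    def test_gfcd_requires_explicit_flag(self):
        d = self.grid_map(np.ones((1, 2, 2)), kind="gfcd")
        with pytest.raises(ValueError, match="explicit|allow_gfcd"):
            log_fcd(d)
        assert log_fcd(d, allow_gfcd=True).kind == "log_gfcd"


class TestSmoothing:
    def test_constant_map_unchanged(self):
        grid = VolumeGrid((8, 8, 8), (2.0, 2.0, 2.0))
        vals = np.full((8, 8, 8), np.nan)
        vals[2:6, 2:6, 2:6] = 1.7
        m = LogFcdMap(grid, vals, kind="srfcd")
        out = smooth_log_fcd(m, 8.0)
        assert np.allclose(out.values[2:6, 2:6, 2:6], 1.7, atol=1e-6)
        assert np.isnan(out.values[0, 0, 0])

    def test_single_present_voxel_unchanged(self):
        grid = VolumeGrid((6, 6, 6), (2.0, 2.0, 2.0))
        vals = np.full((6, 6, 6), np.nan)
        vals[3, 3, 3] = 2.5
        out = smooth_log_fcd(LogFcdMap(grid, vals, kind="srfcd"), 8.0)
        assert out.values[3, 3, 3] == pytest.approx(2.5, abs=1e-9)

    def test_against_kernel_sum_oracle(self):
        rng = np.random.default_rng(4)
        grid = VolumeGrid((7, 7, 7), (2.0, 2.0, 2.0))
        vals = np.full((7, 7, 7), np.nan)
        present = rng.random((7, 7, 7)) < 0.4
        vals[present] = rng.standard_normal(int(present.sum()))
        out = smooth_log_fcd(LogFcdMap(grid, vals, kind="srfcd"), 6.0)
        where = np.argwhere(present)
        for idx in where[rng.choice(len(where), size=min(20, len(where)), replace=False)]:
            expect = masked_smooth_oracle(vals, present, grid, 6.0, idx)
            # the library kernel is truncated; the oracle sums every voxel
            assert out.values[tuple(idx)] == pytest.approx(expect, rel=1e-3, abs=1e-6)

    def test_double_smoothing_rejected(self):
        grid = VolumeGrid((4, 4, 4), (2.0, 2.0, 2.0))
        m = LogFcdMap(grid, np.zeros((4, 4, 4)), kind="srfcd", smoothed=True)
        with pytest.raises(ValueError, match="already smoothed"):
            smooth_log_fcd(m)


class TestParticipantFcd:
    def test_deterministic_and_internally_consistent(self, two_block_bold):
        mask = full_mask_for(two_block_bold)
        a = participant_fcd(two_block_bold, mask)
        b = participant_fcd(two_block_bold, mask)
        assert np.array_equal(a.srfcd.values, b.srfcd.values, equal_nan=True)
        assert np.array_equal(a.lrfcd.values, b.lrfcd.values, equal_nan=True)
        assert np.all(a.gfcd_raw.counts >= a.lfcd_raw.counts)
        assert a.srfcd.smoothed and a.lrfcd.smoothed

    def test_mean_srfcd_recovers_planted_ranking(self):
        from scipy.stats import spearmanr

        from neurofcd.masks_suvr import gray_matter_mask
        from neurofcd.pipeline import _mean_map
        from neurofcd.synthetic import compute_ground_truth, default_study_config, generate_study

        syn = default_study_config(grid_shape=(20, 20, 20), rho_w=0.9, seed=21)
        study = generate_study(syn)
        gm = gray_matter_mask(study.gm_prob)
        maps = [participant_fcd(study.bold[p], gm, FcdConfig(smoothing_fwhm_mm=4.0)).srfcd
                for p in range(syn.n_participants)]
        mean_sr = _mean_map(maps, syn.grid)
        truth = compute_ground_truth(syn)
        sel = ~np.isnan(mean_sr.values) & gm.membership
        rho = spearmanr(mean_sr.values[sel], truth.planted_local_degree[sel]).statistic
        assert rho > 0.5
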