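import numpy as np
import pytest
from scipy.stats import spearmanr

from neurofcd.spin_perm import build_icosphere
from neurofcd.synthetic import (
    HubSpec,
    LongRangePair,
    SyntheticConfig,
    compute_ground_truth,
    default_study_config,
    generate_bold,
    generate_parcellation,
    generate_smooth_vertex_map,
    generate_study,
    generate_suvr_volume,
    generate_tissue_maps,
    gm_region,
)


def hub_config(rho_w=1.0, rho_b=None, n_t=120, seed=0):
    hubs = [HubSpec((1, 1, 1), 1.0, rho_w), HubSpec((4, 4, 4), 1.0, rho_w)]
    pairs = () if rho_b is None else (LongRangePair(0, 1, rho_b),)
    return SyntheticConfig(grid_shape=(6, 6, 6), n_timepoints=n_t, hubs=tuple(hubs),
                           long_range=pairs, seed=seed)


class TestConfigValidation:
    def test_overlapping_hubs_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            SyntheticConfig(grid_shape=(6, 6, 6),
                            hubs=(HubSpec((2, 2, 2), 1.0, 0.9), HubSpec((2, 2, 3), 1.0, 0.9)))

    def test_hub_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            SyntheticConfig(grid_shape=(6, 6, 6), hubs=(HubSpec((0, 0, 0), 1.0, 0.9),))

    def test_pair_correlation_bounded_by_within(self):
        with pytest.raises(ValueError, match="may not exceed"):
            SyntheticConfig(grid_shape=(8, 8, 8),
                            hubs=(HubSpec((2, 2, 2), 1.0, 0.5), HubSpec((5, 5, 5), 1.0, 0.5)),
                            long_range=(LongRangePair(0, 1, 0.8),))


class TestGenerateBold:
    def test_noiseless_hub_is_perfectly_correlated(self):
        bold = generate_bold(hub_config(rho_w=1.0), 0)
        a = bold.data[1, 1, 1]
        b = bold.data[1, 1, 2]  # both inside the first hub
        r = np.corrcoef(a, b)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_no_structure_means_no_edges(self):
        # brute-force pairwise correlations over the whole 6x6x6 grid
        cfg = SyntheticConfig(grid_shape=(6, 6, 6), n_timepoints=120, seed=4)
        bold = generate_bold(cfg, 0)
        flat = bold.data.reshape(-1, cfg.n_timepoints)
        corr = np.corrcoef(flat)
        iu = np.triu_indices_from(corr, k=1)
        frac = float((corr[iu] > 0.6).mean())
        assert frac < 1e-3

    def test_deterministic_per_participant(self):
        cfg = hub_config(rho_w=0.8, seed=9)
        a = generate_bold(cfg, 3)
        b = generate_bold(cfg, 3)
        c = generate_bold(cfg, 4)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_within_hub_correlation_converges_to_rho(self):
        cfg = SyntheticConfig(
            grid_shape=(8, 8, 8), n_timepoints=1200,
            hubs=(HubSpec((3, 3, 3), np.sqrt(2.0), 0.7),), seed=6)
        bold = generate_bold(cfg, 0)
        vox = cfg.hubs[0].voxels()
        series = bold.data[tuple(vox.T)]
        corr = np.corrcoef(series)
        iu = np.triu_indices_from(corr, k=1)
        assert corr[iu].mean() == pytest.approx(0.7, abs=0.05)

    def test_cross_hub_correlation_matches_pair_level(self):
        cfg = hub_config(rho_w=0.9, rho_b=0.6, n_t=1200, seed=2)
        bold = generate_bold(cfg, 0)
        a = bold.data[tuple(cfg.hubs[0].voxels().T)]
        b = bold.data[tuple(cfg.hubs[1].voxels().T)]
        cross = np.array([[np.corrcoef(x, y)[0, 1] for y in b] for x in a])
        assert cross.mean() == pytest.approx(0.6, abs=0.05)

    def test_series_standardized(self):
        bold = generate_bold(hub_config(rho_w=0.8), 0)
        flat = bold.data.reshape(-1, bold.n_timepoints)
        assert np.allclose(flat.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(flat.std(axis=1), 1.0, atol=1e-9)


class TestGroundTruthAndSuvr:
    def test_planted_degrees(self):
        cfg = hub_config(rho_w=0.9, rho_b=0.5)
        truth = compute_ground_truth(cfg)
        vox0 = tuple(cfg.hubs[0].voxels().T)
        assert np.all(truth.planted_local_degree[vox0] == 6)
        assert np.all(truth.planted_long_degree[vox0] == 7)
        outside = truth.planted_local_degree.copy()
        outside[vox0] = 0
        outside[tuple(cfg.hubs[1].voxels().T)] = 0
        assert outside.sum() == 0

    def test_long_degree_only_in_paired_hubs(self):
        cfg = SyntheticConfig(
            grid_shape=(8, 8, 8),
            hubs=(HubSpec((2, 2, 2), 1.0, 0.9), HubSpec((5, 5, 5), 1.0, 0.9),
                  HubSpec((2, 5, 5), 1.0, 0.9)),
            long_range=(LongRangePair(0, 1, 0.5),))
        truth = compute_ground_truth(cfg)
        assert np.all(truth.planted_long_degree[tuple(cfg.hubs[2].voxels().T)] == 0)

    def test_null_coupling_gives_null_correlation(self):
        cfg = default_study_config(coupling_beta=0.0, seed=0)
        truth = compute_ground_truth(cfg)
        region = gm_region(cfg)
        degree = (truth.planted_local_degree + truth.planted_long_degree)[region]
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            cfg_r = default_study_config(coupling_beta=0.0, seed=1000 + rep)
            suvr = generate_suvr_volume(compute_ground_truth(cfg_r), cfg_r)
            rho = spearmanr(suvr.values[region], degree).statistic
            hits += abs(rho) < 0.1
        assert hits >= 0.95 * n_rep

    def test_noiseless_coupling_is_perfectly_monotone(self):
        cfg = default_study_config(suvr_noise_sd=0.0, seed=5)
        truth = compute_ground_truth(cfg)
        suvr = generate_suvr_volume(truth, cfg)
        region = gm_region(cfg)
        degree = (truth.planted_local_degree + truth.planted_long_degree)[region]
        rho = spearmanr(suvr.values[region], degree).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_gm_minimum_above_one(self):
        cfg = default_study_config(seed=8)
        suvr = generate_suvr_volume(compute_ground_truth(cfg), cfg)
        assert suvr.values[gm_region(cfg)].min() > 1.0


class TestTissueAndParcellation:
    def test_tissue_probabilities_valid(self):
        cfg = default_study_config(seed=0)
        wm, gm, csf = generate_tissue_maps(cfg)
        for v in (wm, gm, csf):
            assert v.values.min() >= 0 and v.values.max() <= 1
        assert np.all(wm.values + gm.values + csf.values <= 1 + 1e-9)
        center = tuple((np.asarray(cfg.grid_shape) - 1) // 2)
        assert wm.values[center] >= 0.95
        assert gm.values.max() >= 0.5

    def test_grid_too_small_rejected(self):
        cfg = SyntheticConfig(grid_shape=(8, 8, 8))
        with pytest.raises(ValueError, match="too small"):
            generate_tissue_maps(cfg)

    def test_parcellation_partitions_gm_shell(self):
        cfg = default_study_config(seed=2)
        parc = generate_parcellation(cfg, 4)
        region = gm_region(cfg)
        assert np.array_equal(parc.labels > 0, region)  # union of labels == shell
        assert len(np.unique(parc.labels[region])) == 4  # all labels nonempty

    def test_hubs_keep_one_label(self):
        cfg = default_study_config(seed=2)
        parc = generate_parcellation(cfg, 10)
        for hub in cfg.hubs:
            labs = np.unique(parc.labels[tuple(hub.voxels().T)])
            assert len(labs) == 1 and labs[0] > 0

    def test_spinnable_flag_propagates(self):
        cfg = default_study_config(seed=2)
        parc = generate_parcellation(cfg, 10, non_spinnable=(3,))
        assert parc.label_table[3].spinnable is False
        assert parc.label_table[4].spinnable is True

    def test_network_groups_cycle(self):
        cfg = default_study_config(seed=2)
        parc = generate_parcellation(cfg, 10)
        assert parc.label_table[1].group == parc.label_table[8].group  # 7-cycle


class TestSmoothVertexMap:
    def test_nearby_vertices_strongly_correlated(self):
        mesh = build_icosphere(3)
        # the two closest distinct vertices on the right hemisphere
        sel = mesh.hemisphere_index("R")
        v = mesh.vertices[sel]
        d = np.linalg.norm(v[0] - v[1:40], axis=1)
        j = int(np.argmin(d)) + 1
        vals = np.array([
            generate_smooth_vertex_map(mesh, 1.0, seed=s).values[[sel[0], sel[j]]]
            for s in range(500)
        ])
        r = np.corrcoef(vals[:, 0], vals[:, 1])[0, 1]
        assert r > 0.8

    def test_antipodal_vertices_uncorrelated_at_short_length(self):
        mesh = build_icosphere(2)
        sel = mesh.hemisphere_index("R")
        v = mesh.vertices[sel]
        j = int(np.argmin(np.linalg.norm(v + v[0], axis=1)))  # nearest to -v0
        vals = np.array([
            generate_smooth_vertex_map(mesh, 0.2, seed=s).values[[sel[0], sel[j]]]
            for s in range(500)
        ])
        r = np.corrcoef(vals[:, 0], vals[:, 1])[0, 1]
        assert abs(r) < 0.15

    def test_deterministic(self):
        mesh = build_icosphere(2)
        a = generate_smooth_vertex_map(mesh, 0.5, seed=7)
        b = generate_smooth_vertex_map(mesh, 0.5, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_hemispheres_independent(self):
        mesh = build_icosphere(2)
        m = generate_smooth_vertex_map(mesh, 0.5, seed=1)
        left = m.values[mesh.hemisphere_index("L")]
        right = m.values[mesh.hemisphere_index("R")]
        assert not np.allclose(left, right)


class TestFullStudy:
    def test_generation_fast_and_deterministic(self):
        import time

        t0 = time.time()
        cfg = default_study_config(seed=12)
        study = generate_study(cfg)
        elapsed = time.time() - t0
        assert elapsed < 60.0
        assert len(study.bold) == cfg.n_participants
        study2 = generate_study(default_study_config(seed=12))
        assert np.array_equal(study.bold[0].data, study2.bold[0].data)
        assert np.array_equal(study.pet[3].values, study2.pet[3].values)
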