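import numpy as np
import pytest
from scipy import stats as sps

from olfmri.cohort import (
    ClusterSpec,
    CohortConfig,
    CouplingSpec,
    StaircaseConfig,
    generate_atlas,
    generate_cohort,
    generate_gm_cohort,
    generate_motion_traces,
    generate_olfactory_scores,
    generate_roi_timeseries,
    simulate_staircase,
    tdi_score,
)
from olfmri.prep import framewise_displacement


def small_cfg(**kw):
    base = dict(
        n_group_a=4,
        n_group_b=4,
        grid_shape=(10, 10, 10),
        voxel_size_mm=3.0,
        n_rois=6,
        n_volumes=60,
        n_unscored_b=0,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestConfigValidation:
    def test_cluster_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside grid"):
            small_cfg(planted_clusters=(ClusterSpec((9, 5, 5), 3),))

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            ClusterSpec((5, 5, 5), 2, effect_size=-1.0)

    def test_odd_roi_count_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(n_rois=7)

    def test_coupling_self_edge_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec(seed_roi=1, target_roi=1)

    def test_burst_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec(1, 2, burst_fraction=1.5)

    def test_tdi_mean_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(tdi_mean_a=50.0)


class TestDeterminism:
    def test_same_seed_bit_identical_cohort(self):
        cfg = small_cfg(
            planted_clusters=(ClusterSpec((5, 5, 5), 2, "pattern", 2.0),),
            coupling_edges=(CouplingSpec(1, 2, "A", 0.5, 0.9),),
            seed=5,
        )
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        for s1, s2 in zip(c1.subjects, c2.subjects):
            np.testing.assert_array_equal(s1.gm_map.values, s2.gm_map.values)
            np.testing.assert_array_equal(s1.roi_ts.data, s2.roi_ts.data)
            np.testing.assert_array_equal(s1.motion, s2.motion)
            assert (s1.olfactory is None) == (s2.olfactory is None)
            if s1.olfactory is not None:
                assert s1.olfactory == s2.olfactory
        np.testing.assert_array_equal(c1.atlas.labels, c2.atlas.labels)

    def test_different_seed_differs(self):
        m1, _ = generate_gm_cohort(small_cfg(seed=1))
        m2, _ = generate_gm_cohort(small_cfg(seed=2))
        assert not np.array_equal(m1[0].values, m2[0].values)


class TestGreyMatterGeneration:
    def test_maps_share_grid_and_are_nonnegative(self):
        maps, _ = generate_gm_cohort(small_cfg())
        assert len(maps) == 8
        for m in maps:
            assert m.values.shape == (10, 10, 10)
            assert np.all(m.values >= 0)

    def test_planted_pattern_separates_groups(self):
        cfg = small_cfg(
            n_group_a=10,
            n_group_b=10,
            planted_clusters=(ClusterSpec((5, 5, 5), 2, "pattern", 3.0),),
            seed=3,
        )
        maps, truth = generate_gm_cohort(cfg)
        vox = truth[0]
        flat = np.stack([m.values[vox] for m in maps])
        # per-voxel group difference is a strong effect in within-group SD units
        diff = flat[:10].mean(axis=0) - flat[10:].mean(axis=0)
        sd = np.sqrt(0.5 * (flat[:10].var(axis=0) + flat[10:].var(axis=0)))
        d = np.abs(diff) / sd
        assert d.mean() > 2.0
        assert np.all(d > 0.8)

    def test_null_cohorts_exchangeable_subject_means(self):
        # with no planted effect the groups' subject-mean distributions agree
        rejections = 0
        for seed in range(20):
            cfg = CohortConfig(
                n_group_a=10,
                n_group_b=10,
                grid_shape=(10, 10, 10),
                voxel_size_mm=3.0,
                n_rois=4,
                n_volumes=30,
                n_unscored_b=0,
                seed=seed,
            )
            maps, _ = generate_gm_cohort(cfg)
            means = np.array([m.values[m.brain_mask].mean() for m in maps])
            p = sps.ks_2samp(means[:10], means[10:]).pvalue
            rejections += p < 0.01
        assert rejections <= 2


class TestROITimeseries:
    def test_full_record_coupling_drives_correlation_to_one(self):
        cfg = small_cfg(
            n_volumes=216, coupling_edges=(CouplingSpec(1, 2, "both", 1.0, 0.99),)
        )
        ts, truth = generate_roi_timeseries(cfg)
        for t in ts:
            assert np.corrcoef(t.data[0], t.data[1])[0, 1] > 0.95
        assert len(truth) == cfg.n_subjects

    def test_zero_burst_fraction_leaves_edges_independent(self):
        cfg = small_cfg(
            n_volumes=216, coupling_edges=(CouplingSpec(1, 2, "both", 0.0, 0.9),)
        )
        ts, truth = generate_roi_timeseries(cfg)
        assert truth == []
        rs = [abs(np.corrcoef(t.data[0], t.data[1])[0, 1]) for t in ts]
        assert np.mean(rs) < 0.25

    def test_group_restricted_edge_only_in_group_a(self):
        cfg = small_cfg(
            n_group_a=6,
            n_group_b=6,
            n_volumes=216,
            coupling_edges=(CouplingSpec(1, 2, "A", 0.5, 0.9),),
            seed=9,
        )
        ts, truth = generate_roi_timeseries(cfg)
        assert {t["subject_id"] for t in truth} == set(cfg.subject_ids[:6])

    def test_matrix_shape_and_labels(self):
        ts, _ = generate_roi_timeseries(small_cfg())
        assert ts[0].data.shape == (6, 60)
        assert list(ts[0].roi_labels) == [1, 2, 3, 4, 5, 6]


class TestMotionTraces:
    def test_fd_calibrated_to_group_targets(self):
        cfg = small_cfg(n_group_a=20, n_group_b=20, n_volumes=216, seed=4)
        traces = generate_motion_traces(cfg)
        fd = np.array([framewise_displacement(t).mean_fd for t in traces])
        assert fd[:20].mean() == pytest.approx(cfg.fd_mean_a, abs=0.02)
        assert fd[20:].mean() == pytest.approx(cfg.fd_mean_b, abs=0.02)

    def test_equal_group_targets_no_systematic_difference(self):
        hits = 0
        for seed in range(30):
            cfg = small_cfg(
                n_group_a=10, n_group_b=10, n_volumes=120, seed=seed,
                fd_mean_a=0.12, fd_mean_b=0.12,
            )
            traces = generate_motion_traces(cfg)
            fd = np.array([framewise_displacement(t).mean_fd for t in traces])
            p = sps.ttest_ind(fd[:10], fd[10:]).pvalue
            hits += p < 0.05
        assert hits <= 4  # ~5 % nominal false-positive rate


class TestAtlas:
    def test_paired_mirrored_parcellation(self):
        cfg = CohortConfig(grid_shape=(24, 28, 24), n_rois=96, n_volumes=216)
        atlas = generate_atlas(cfg)
        meta = atlas.meta
        assert len(meta) == 96
        assert (meta["hemisphere"] == "L").sum() == 48
        # involution and bijectivity
        part = dict(zip(meta["label"], meta["partner_label"]))
        assert all(part[part[k]] == k for k in part)
        # x-flip maps every label onto its partner
        flipped = atlas.labels[::-1, :, :]
        lab = atlas.labels[atlas.labels > 0]
        mapped = np.vectorize(part.get)(atlas.labels[atlas.labels > 0])
        np.testing.assert_array_equal(flipped[atlas.labels > 0], mapped)

    def test_seed_classes_marked(self):
        atlas = generate_atlas(small_cfg())
        assert set(atlas.meta.loc[atlas.meta["is_seed"], "seed_class"]) == {
            "APC",
            "PPC",
            "OFC",
        }

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_atlas(CohortConfig(grid_shape=(4, 4, 4), n_rois=96, n_volumes=216))


class TestStaircase:
    def test_deterministic_given_seed(self):
        sc = StaircaseConfig(true_threshold_step=8, seed=7)
        r1, r2 = simulate_staircase(sc), simulate_staircase(sc)
        assert r1.trials.equals(r2.trials)
        assert r1.threshold == r2.threshold

    def test_score_bounded_by_dilution_series(self):
        for seed in range(20):
            r = simulate_staircase(StaircaseConfig(true_threshold_step=1.0, seed=seed))
            if r.complete:
                assert 1.0 <= r.threshold <= 16.0

    def test_exhausted_budget_flags_incomplete(self):
        r = simulate_staircase(StaircaseConfig(true_threshold_step=8, max_trials=3, seed=0))
        assert not r.complete
        assert r.threshold is None

    def test_recovery_bias_below_one_step(self):
        scores = [
            simulate_staircase(
                StaircaseConfig(true_threshold_step=8, lapse_rate=0.0, seed=s)
            ).threshold
            for s in range(300)
        ]
        scores = np.array([s for s in scores if s is not None])
        assert abs(scores.mean() - 8.0) < 1.0
        assert np.mean(np.abs(scores - 8.0) <= 1.0) >= 0.75

    def test_scored_reversals_cannot_exceed_collected(self):
        with pytest.raises(ValueError):
            StaircaseConfig(n_reversals_stop=4, n_reversals_scored=7)


class TestTDIScore:
    @pytest.mark.parametrize(
        "t, d, i, expected",
        [(16, 16, 16, 48.0), (0, 0, 0, 0.0), (5.25, 4, 4, 13.25)],
    )
    def test_sum_score(self, t, d, i, expected):
        assert tdi_score(t, d, i).tdi == expected

    def test_out_of_range_component_rejected(self):
        with pytest.raises(ValueError):
            tdi_score(17, 0, 0)
        with pytest.raises(ValueError):
            tdi_score(5, -1, 0)

    def test_non_integer_subtest_rejected(self):
        with pytest.raises(ValueError):
            tdi_score(5.0, 4.5, 4)

    def test_generated_scores_near_group_means_and_conserved(self):
        cfg = CohortConfig(grid_shape=(10, 10, 10), n_rois=4, n_volumes=30, seed=13)
        scores = generate_olfactory_scores(cfg)
        labels = cfg.group_labels
        a = [s.tdi for s, g in zip(scores, labels) if g == "A"]
        b = [s.tdi for s, g in zip(scores, labels) if g == "B" and s is not None]
        assert np.mean(a) == pytest.approx(cfg.tdi_mean_a, abs=2.0)
        assert np.mean(b) == pytest.approx(cfg.tdi_mean_b, abs=2.0)
        assert sum(s is None for s in scores) == 3
        for s in scores:
            if s is not None:
                assert s.tdi == s.threshold + s.discrimination + s.identification
                assert s.tdi <= 48
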