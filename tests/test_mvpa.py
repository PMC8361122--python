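import numpy as np
import pytest
from sklearn.svm import LinearSVC

from olfmri.mvpa import (
    AccuracyMap,
    ClusterCriteria,
    GreyMatterMap,
    PermutationSpec,
    SearchlightSpec,
    _svm_decision,
    build_searchlight,
    cluster_univariate_test,
    make_fold_scheme,
    permutation_test_cluster,
    searchlight_classify,
    threshold_clusters,
)


def brute_force_sphere(center, mask, voxel, radius):
    """Enumerate in-mask voxels within world distance `radius` of center."""
    out = []
    for idx in np.ndindex(mask.shape):
        if mask[idx] and np.linalg.norm((np.array(idx) - center) * voxel) <= radius:
            out.append(np.ravel_multi_index(idx, mask.shape))
    return np.sort(out)


class TestSearchlightGeometry:
    def test_sphere_size_on_2mm_grid(self):
        # 6 mm radius on an isotropic 2 mm grid: brute-force count is 123
        mask = np.ones((9, 9, 9), dtype=bool)
        sl = build_searchlight(mask, 2.0, SearchlightSpec(radius_mm=6.0))
        center_pos = np.flatnonzero((sl.centers == 4).all(axis=1))[0]
        assert len(sl.members[center_pos]) == 123

    def test_members_match_brute_force_on_random_centers(self, rng):
        mask = rng.random((8, 8, 8)) > 0.3
        mask[4, 4, 4] = True
        sl = build_searchlight(mask, 2.5, SearchlightSpec(radius_mm=6.0))
        for i in rng.choice(len(sl.members), size=20, replace=False):
            expected = brute_force_sphere(sl.centers[i], mask, 2.5, 6.0)
            np.testing.assert_array_equal(sl.members[i], expected)

    def test_boundary_sphere_clipped_never_empty(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[0, 0, 0] = True
        sl = build_searchlight(mask, 3.0, SearchlightSpec(radius_mm=6.0))
        assert len(sl.members) == 1
        assert len(sl.members[0]) == 1

    def test_min_voxels_drops_sparse_centers(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[3, 3, 3] = True
        mask[0, 0, 0] = True
        sl = build_searchlight(
            mask, 3.0, SearchlightSpec(radius_mm=6.0, min_voxels_per_sphere=2)
        )
        assert len(sl.members) == 0  # isolated voxels have singleton spheres

    def test_radius_below_voxel_rejected(self):
        with pytest.raises(ValueError):
            build_searchlight(np.ones((4, 4, 4), bool), 3.0, SearchlightSpec(radius_mm=2.0))


class TestFoldScheme:
    def test_study_design_arithmetic(self):
        labels = np.array(["A"] * 20 + ["B"] * 23)
        fs = make_fold_scheme(labels, n_folds=10, seed=0)
        assert len(fs.folds) == 10
        for train, test in fs.folds:
            assert train.size == 38 and test.size == 2
            assert (labels[train] == "A").sum() == 19
            assert (labels[train] == "B").sum() == 19
            assert set(test) & set(train) == set()
            assert {labels[t] for t in test} == {"A", "B"}

    def test_every_subject_trains_at_least_once(self):
        labels = np.array(["A"] * 20 + ["B"] * 23)
        for seed in range(5):
            fs = make_fold_scheme(labels, n_folds=10, seed=seed)
            trained = set()
            for train, _ in fs.folds:
                trained |= set(train.tolist())
            assert trained == set(range(43))

    def test_smallest_case_exhaustive_pairs(self):
        labels = np.array(["A", "A", "B", "B"])
        fs = make_fold_scheme(labels, n_folds=2, train_per_group=1, seed=0)
        tested = set()
        for train, test in fs.folds:
            assert train.size == 2 and test.size == 2
            tested |= set(test.tolist())
        assert tested == {0, 1, 2, 3}

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_fold_scheme(np.array(["A", "B", "B"]), n_folds=2)


def _const_maps(n, shape=(8, 8, 8)):
    mask = np.ones(shape, dtype=bool)
    aff = np.eye(4)
    return [
        GreyMatterMap(np.full(shape, 0.5), 3.0, aff, mask) for _ in range(n)
    ]


class TestSearchlightClassify:
    def test_degenerate_constant_maps_score_chance(self):
        maps = _const_maps(8)
        labels = np.array(["A"] * 4 + ["B"] * 4)
        sl = build_searchlight(maps[0].brain_mask, 3.0, SearchlightSpec())
        fs = make_fold_scheme(labels, n_folds=4, seed=0)
        acc = searchlight_classify(maps, labels, sl, fs)
        assert np.all(acc.values[acc.mask] == 0.5)

    def test_planted_cluster_recovered(self, planted_cohort):
        cfg, maps, truth = planted_cohort
        labels = cfg.group_labels
        sl = build_searchlight(maps[0].brain_mask, cfg.voxel_size_mm, SearchlightSpec())
        fs = make_fold_scheme(labels, n_folds=10, seed=0)
        acc = searchlight_classify(maps, labels, sl, fs)
        inside = np.nanmean(acc.values[truth[0] & acc.mask])
        assert inside > 0.70
        clusters = threshold_clusters(acc, ClusterCriteria(), maps[0].affine)
        assert clusters and truth[0][clusters[0].peak_index]

    def test_solver_matches_public_estimator(self, rng):
        for n, p in ((30, 12), (20, 50)):
            X = rng.normal(size=(n, p))
            y = np.r_[np.zeros(n // 2), np.ones(n - n // 2)].astype(int)
            w, b = _svm_decision(X, y, C=1.0)
            ref = LinearSVC(C=1.0, dual=(n < p), random_state=0).fit(X, y)
            Xt = rng.normal(size=(100, p))
            ours = (Xt @ w + b > 0).astype(int)
            assert np.mean(ours == ref.predict(Xt)) == 1.0


def _acc_map(values):
    mask = np.isfinite(values)
    return AccuracyMap(values=values, mask=mask, n_test_per_center=20)


class TestThresholdClusters:
    def test_all_chance_map_yields_nothing(self):
        vals = np.full((10, 10, 10), 0.5)
        assert threshold_clusters(_acc_map(vals), ClusterCriteria(min_cluster_size=5), np.eye(4)) == []

    def test_size_rule_strictly_greater(self):
        vals = np.full((20, 20, 20), 0.5)
        vals[1:6, 1:7, 1:6] = 0.8  # 150 voxels
        vals[10:14, 10:15, 10:14] = 0.9  # 80 voxels
        crit = ClusterCriteria(acc_threshold=0.70, min_cluster_size=100)
        recs = threshold_clusters(_acc_map(vals), crit, np.eye(4))
        assert len(recs) == 1
        assert recs[0].cluster_size == 150
        # exact boundary: a 100-voxel blob must NOT survive size > 100
        vals2 = np.full((20, 20, 20), 0.5)
        vals2[1:5, 1:6, 1:6] = 0.9  # 100 voxels
        assert threshold_clusters(_acc_map(vals2), crit, np.eye(4)) == []

    def test_threshold_strictly_greater(self):
        vals = np.full((10, 10, 10), 0.70)  # exactly at threshold: excluded
        crit = ClusterCriteria(min_cluster_size=5)
        assert threshold_clusters(_acc_map(vals), crit, np.eye(4)) == []

    def test_peak_in_world_coordinates(self):
        vals = np.full((12, 12, 12), 0.5)
        vals[2:7, 2:7, 2:7] = 0.8
        vals[4, 4, 4] = 0.95
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = -10
        recs = threshold_clusters(_acc_map(vals), ClusterCriteria(min_cluster_size=50), aff)
        assert recs[0].peak_index == (4, 4, 4)
        assert recs[0].peak_coord_world == (-2.0, -2.0, -2.0)
        assert recs[0].peak_accuracy == pytest.approx(0.95)

    def test_deterministic_tie_break(self):
        vals = np.full((12, 12, 12), 0.5)
        vals[2:8, 2:8, 2:8] = 1.0  # fully saturated blob
        recs = threshold_clusters(_acc_map(vals), ClusterCriteria(min_cluster_size=50), np.eye(4))
        recs2 = threshold_clusters(_acc_map(vals), ClusterCriteria(min_cluster_size=50), np.eye(4))
        assert recs[0].peak_index == recs2[0].peak_index
        # centre-seeking: the tied peak sits at the blob centre, not a corner
        assert recs[0].peak_index in {(4, 4, 4), (5, 5, 5), (4, 4, 5), (4, 5, 4),
                                      (5, 4, 4), (4, 5, 5), (5, 4, 5), (5, 5, 4)}


class TestPermutationTest:
    def test_degenerate_maps_give_p_one(self):
        # constant maps: every accuracy (observed and permuted) is chance
        maps = _const_maps(8)
        labels = np.array(["A"] * 4 + ["B"] * 4)
        from olfmri.mvpa import ClusterRecord

        cl = ClusterRecord(1, np.arange(20), (0, 0, 0), (0, 0, 0), 20, 0.5)
        permutation_test_cluster(
            cl, maps, labels, PermutationSpec(n_resamplings=19, seed=0), n_folds=4
        )
        assert cl.perm_p == 1.0
        assert cl.observed_accuracy == 0.5

    def test_planted_cluster_reaches_p_floor(self, planted_cohort):
        cfg, maps, truth = planted_cohort
        from olfmri.mvpa import ClusterRecord

        member = np.flatnonzero(truth[0].reshape(-1))
        cl = ClusterRecord(1, member, (7, 7, 7), (0, 0, 0), member.size, 1.0)
        permutation_test_cluster(
            cl, maps, cfg.group_labels, PermutationSpec(n_resamplings=49, seed=1)
        )
        assert cl.perm_p == pytest.approx(1 / 50)

    def test_zero_resamplings_rejected(self):
        with pytest.raises(ValueError):
            PermutationSpec(n_resamplings=0)


class TestUnivariateFollowUp:
    def test_df_matches_design_and_toy_t(self, planted_cohort):
        cfg, maps, truth = planted_cohort
        from olfmri.mvpa import ClusterRecord

        member = np.flatnonzero(truth[0].reshape(-1))
        cl = ClusterRecord(1, member, (7, 7, 7), (0, 0, 0), member.size, 1.0)
        means, res = cluster_univariate_test(maps, cfg.group_labels, cl)
        assert means.shape == (40,)
        assert res.df == 38

    def test_empty_cluster_rejected(self, planted_cohort):
        cfg, maps, _ = planted_cohort
        from olfmri.mvpa import ClusterRecord

        cl = ClusterRecord(1, np.array([], dtype=int), (0, 0, 0), (0, 0, 0), 0, 0.5)
        with pytest.raises(ValueError):
            cluster_univariate_test(maps, cfg.group_labels, cl)
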