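"""Whole-brain searchlight classification of grey-matter volume.

A 6 mm-radius sphere is slid over every voxel of the brain mask; at each
position a linear max-margin classifier (liblinear, C = 1) is trained to
separate the two groups from the sphere's voxel values, under a balanced
cross-validation in which every fold trains on an equal number of subjects
per group and tests on one held-out subject from each group. The mean
test accuracy across folds is written to the sphere's centre voxel,
producing an accuracy map. Supra-threshold connected components
(accuracy > 0.70, size > 100 voxels by default) are then submitted to a
label-permutation test: the cross-validated accuracy over the cluster's
voxels is recomputed under randomly permuted group labels and the p-value
is the add-one-smoothed exceedance probability of the observed accuracy.

Univariate follow-ups (pooled-variance t-test on per-subject cluster mean
volume; Pearson/Spearman correlation with the behavioural score) live here
as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sklearn
from scipy import ndimage
from sklearn.svm import LinearSVC

from .stats import CorrelationResult, TTestResult, correlate, pooled_ttest

__all__ = [
    "GreyMatterMap",
    "SearchlightSpec",
    "Searchlight",
    "FoldScheme",
    "AccuracyMap",
    "ClusterCriteria",
    "ClusterRecord",
    "PermutationSpec",
    "build_searchlight",
    "make_fold_scheme",
    "searchlight_classify",
    "threshold_clusters",
    "cluster_cv_accuracy",
    "permutation_test_cluster",
    "cluster_univariate_test",
    "correlate_with_behavior",
]

CHANCE = 0.5


@dataclass
class GreyMatterMap:
    """Modulated grey-matter volume of one subject on a common grid."""

    values: np.ndarray
    voxel_size_mm: float
    affine: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.values.ndim != 3 or self.values.shape != self.brain_mask.shape:
            raise ValueError("values and brain_mask must be identically shaped 3-D grids")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if np.any(self.values[self.brain_mask] < 0):
            raise ValueError("grey-matter values must be nonnegative inside the mask")


@dataclass(frozen=True)
class SearchlightSpec:
    radius_mm: float = 6.0
    min_voxels_per_sphere: int = 1

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.min_voxels_per_sphere < 1:
            raise ValueError("min_voxels_per_sphere must be >= 1")


@dataclass
class Searchlight:
    """Centre voxels and their sphere members (flat indices into the grid)."""

    shape: tuple[int, int, int]
    centers: np.ndarray  # (N, 3) voxel indices, lexicographic order
    center_flat: np.ndarray  # (N,)
    members: list[np.ndarray]  # per centre, flat indices of member voxels


@dataclass
class FoldScheme:
    """Balanced cross-validation folds.

    Each fold trains on ``train_per_group`` subjects from each group and
    tests on exactly one held-out subject per group. Across folds every
    subject enters at least one training set.
    """

    folds: list[tuple[np.ndarray, np.ndarray]]
    train_per_group: int
    seed: int


@dataclass
class AccuracyMap:
    values: np.ndarray  # 3-D, NaN outside evaluated centres
    mask: np.ndarray  # evaluated centres
    n_test_per_center: int

    def spatial_mean(self) -> float:
        return float(np.nanmean(self.values[self.mask]))

    def chance_se(self) -> float:
        """Binomial SE of one centre's accuracy estimate under chance."""
        return float(np.sqrt(0.25 / self.n_test_per_center))


@dataclass(frozen=True)
class ClusterCriteria:
    acc_threshold: float = 0.70
    min_cluster_size: int = 100
    connectivity: int = 26

    def __post_init__(self):
        if not (0.5 < self.acc_threshold < 1):
            raise ValueError("acc_threshold must lie in (0.5, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class ClusterRecord:
    label: int
    member_flat: np.ndarray
    peak_index: tuple[int, int, int]
    peak_coord_world: tuple[float, float, float]
    cluster_size: int
    peak_accuracy: float
    perm_p: float | None = None
    observed_accuracy: float | None = None


@dataclass(frozen=True)
class PermutationSpec:
    n_resamplings: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.n_resamplings < 1:
            raise ValueError("n_resamplings must be >= 1")


def build_searchlight(
    mask: np.ndarray, voxel_size_mm: float, spec: SearchlightSpec
) -> Searchlight:
    """Index every in-mask voxel's spherical neighbourhood.

    A voxel belongs to the sphere at a centre iff its centre-to-centre
    world distance is <= radius_mm and it lies inside the brain mask.
    Centres whose (mask-clipped) sphere has fewer than
    ``min_voxels_per_sphere`` members are dropped.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if spec.radius_mm < voxel_size_mm:
        raise ValueError("searchlight radius smaller than a voxel")
    r_vox = int(np.floor(spec.radius_mm / voxel_size_mm))
    rng_off = np.arange(-r_vox, r_vox + 1)
    ox, oy, oz = np.meshgrid(rng_off, rng_off, rng_off, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    dist = np.linalg.norm(offsets * voxel_size_mm, axis=1)
    offsets = offsets[dist <= spec.radius_mm]

    coords = np.argwhere(mask)  # lexicographic
    shape = mask.shape
    members_matrix = np.full((coords.shape[0], offsets.shape[0]), -1, dtype=np.int64)
    for j, off in enumerate(offsets):
        p = coords + off
        ok = np.all((p >= 0) & (p < np.asarray(shape)), axis=1)
        flat = np.ravel_multi_index(p[ok].T, shape)
        inmask = mask.reshape(-1)[flat]
        rows = np.flatnonzero(ok)[inmask]
        members_matrix[rows, j] = flat[inmask]

    members = []
    keep = []
    for i in range(coords.shape[0]):
        m = members_matrix[i]
        m = m[m >= 0]
        if m.size >= spec.min_voxels_per_sphere:
            members.append(np.sort(m))
            keep.append(i)
    keep = np.asarray(keep, dtype=int)
    coords = coords[keep]
    return Searchlight(
        shape=shape,
        centers=coords,
        center_flat=np.ravel_multi_index(coords.T, shape),
        members=members,
    )


def _group_indices(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two group labels required")
    return np.flatnonzero(labels == groups[0]), np.flatnonzero(labels == groups[1])


def make_fold_scheme(
    labels,
    n_folds: int = 10,
    train_per_group: int | None = None,
    seed: int = 0,
) -> FoldScheme:
    """Balanced folds: equal training counts per group, one test pair each.

    With the smaller group of size n, the default trains on n - 1 subjects
    per group (the larger group's training subjects are semi-randomly
    subsampled to match). Test subjects are drawn without replacement
    across folds as long as the group lasts. A deterministic fix-up
    guarantees every subject appears in at least one training set.
    """
    idx_a, idx_b = _group_indices(labels)
    na, nb = idx_a.size, idx_b.size
    tpg = train_per_group if train_per_group is not None else min(na, nb) - 1
    if tpg < 1 or na < tpg + 1 or nb < tpg + 1:
        raise ValueError(
            f"groups of {na} and {nb} too small for train_per_group={tpg}"
        )
    rng = np.random.default_rng(seed)
    test_a = np.concatenate(
        [rng.permutation(idx_a) for _ in range(-(-n_folds // na))]
    )[:n_folds]
    test_b = np.concatenate(
        [rng.permutation(idx_b) for _ in range(-(-n_folds // nb))]
    )[:n_folds]

    folds: list[tuple[np.ndarray, np.ndarray]] = []
    train_sets: list[set[int]] = []
    for f in range(n_folds):
        pool_a = idx_a[idx_a != test_a[f]]
        pool_b = idx_b[idx_b != test_b[f]]
        tr_a = pool_a if pool_a.size == tpg else rng.choice(pool_a, tpg, replace=False)
        tr_b = pool_b if pool_b.size == tpg else rng.choice(pool_b, tpg, replace=False)
        train = np.sort(np.concatenate([tr_a, tr_b]))
        test = np.array([test_a[f], test_b[f]])
        folds.append((train, test))
        train_sets.append(set(train.tolist()))

    # coverage fix-up: swap never-trained subjects into a fold where legal
    all_subjects = set(range(np.asarray(labels).size))
    trained = set().union(*train_sets)
    for s in sorted(all_subjects - trained):
        g_pool = idx_a if s in idx_a else idx_b
        for f in range(n_folds):
            train, test = folds[f]
            if s in test:
                continue
            same_group = [t for t in train if t in g_pool]
            # replace a subject that trains elsewhere too
            repl = next(
                (t for t in same_group if sum(t in ts for ts in train_sets) > 1), None
            )
            if repl is None:
                continue
            new_train = np.sort(np.where(train == repl, s, train))
            folds[f] = (new_train, test)
            train_sets[f] = set(new_train.tolist())
            break
    return FoldScheme(folds=folds, train_per_group=tpg, seed=seed)


def _preprocess(Xtr, Xte, mode: str):
    """Feature conditioning fit on the training fold only (no leakage).

    ``center`` (default): subtract the per-feature training mean and divide
    by one global scalar (the pooled training SD), which preserves the
    multivoxel pattern while putting the margin problem at unit scale --
    raw modulated GM values (offset ~0.5, tiny variance) condition the
    solver poorly. ``zscore``: full per-feature standardization.
    ``none``: raw values.
    """
    if mode == "none":
        return Xtr, Xte
    mu = Xtr.mean(axis=0)
    Xtr = Xtr - mu
    Xte = Xte - mu
    if mode == "center":
        s = Xtr.std()
        if s > 0:
            Xtr = Xtr / s
            Xte = Xte / s
    elif mode == "zscore":
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = Xtr / sd
        Xte = Xte / sd
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return Xtr, Xte


try:  # low-overhead entry point of scikit-learn's bundled liblinear
    from sklearn.svm import _liblinear as _liblinear_backend

    _liblinear_backend.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - fallback for other sklearn builds
    _liblinear_backend = None

_SOLVER_PRIMAL = 2  # LinearSVC(loss="squared_hinge", dual=False)
_SOLVER_DUAL = 1  # LinearSVC(loss="squared_hinge", dual=True)


def _svm_decision(Xtr: np.ndarray, ytr: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Weight vector and bias of the linear max-margin classifier.

    Identical model to ``LinearSVC(C=C, dual="auto")`` -- liblinear's
    squared-hinge SVM, solved in the primal when samples outnumber
    features and in the dual otherwise (a unit test asserts prediction
    agreement with the public estimator). Calling the solver directly
    avoids per-fit estimator overhead, which matters at ~1e5 fits per
    permutation run; the dual seed is fixed for determinism.
    """
    dual = Xtr.shape[0] < Xtr.shape[1]
    if _liblinear_backend is not None:
        Xtr = np.ascontiguousarray(Xtr, dtype=np.float64)
        yt = np.require(np.asarray(ytr, dtype=np.float64), requirements="W")
        raw, _ = _liblinear_backend.train_wrap(
            Xtr,
            yt,
            False,
            _SOLVER_DUAL if dual else _SOLVER_PRIMAL,
            1e-4,
            1.0,
            float(C),
            np.ones(2),
            1000,
            0,
            0.1,
            np.ones(Xtr.shape[0]),
        )
        return raw[0, :-1], float(raw[0, -1])
    clf = LinearSVC(C=C, dual=dual, random_state=0)
    clf.fit(Xtr, ytr)
    return clf.coef_.ravel(), float(clf.intercept_[0])


def _fit_accuracy(Xtr, ytr, Xte, yte, C: float) -> float:
    """Test accuracy of a linear max-margin classifier on one feature set."""
    if np.all(np.ptp(Xtr, axis=0) == 0):
        return CHANCE  # degenerate sphere: no information, defined as chance
    w, b = _svm_decision(Xtr, ytr, C)
    pred = (Xte @ w + b > 0).astype(int)
    return float(np.mean(pred == yte))


def searchlight_classify(
    maps: list[GreyMatterMap],
    labels,
    sl: Searchlight,
    folds: FoldScheme,
    C: float = 1.0,
    scaling: str = "center",
) -> AccuracyMap:
    """Mean cross-validated accuracy at every searchlight centre.

    Feature conditioning (see ``_preprocess``) uses training-fold
    statistics only, never the test pair.
    """
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1 or next(iter(shapes)) != sl.shape:
        raise ValueError("all maps must share the searchlight grid")
    y = _binary_labels(labels)
    X = np.stack([m.values.reshape(-1) for m in maps])
    acc = np.zeros(len(sl.members))
    with sklearn.config_context(assume_finite=True):
        for train, test in folds.folds:
            ytr, yte = y[train], y[test]
            Xtr_full, Xte_full = X[train], X[test]
            for i, mem in enumerate(sl.members):
                Xtr, Xte = _preprocess(Xtr_full[:, mem], Xte_full[:, mem], scaling)
                acc[i] += _fit_accuracy(Xtr, ytr, Xte, yte, C)
    acc /= len(folds.folds)
    values = np.full(sl.shape, np.nan)
    values.reshape(-1)[sl.center_flat] = acc
    mask = np.zeros(sl.shape, dtype=bool)
    mask.reshape(-1)[sl.center_flat] = True
    n_test = len(folds.folds) * len(folds.folds[0][1])
    return AccuracyMap(values=values, mask=mask, n_test_per_center=n_test)


def _binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two group labels required")
    return (labels == groups[1]).astype(int)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def threshold_clusters(
    acc: AccuracyMap, crit: ClusterCriteria, affine: np.ndarray
) -> list[ClusterRecord]:
    """Supra-threshold connected components of the accuracy map.

    Voxels with accuracy strictly above ``acc_threshold`` are grouped with
    the chosen 3-D neighbourhood; components strictly larger than
    ``min_cluster_size`` are kept. The peak is the maximum-accuracy voxel,
    reported in world coordinates through the map's affine. When several
    voxels tie at the maximum (accuracy saturates over the informative
    region), the tie goes to the voxel nearest the accuracy-weighted
    centroid of the component -- the centre of the informative region --
    with any residual tie broken by lexicographic grid order, so the peak
    stays deterministic.
    """
    supra = np.where(np.isfinite(acc.values), acc.values > crit.acc_threshold, False)
    lab, n = ndimage.label(supra, structure=_STRUCTURES[crit.connectivity])
    records: list[ClusterRecord] = []
    out_label = 0
    for comp in range(1, n + 1):
        coords = np.argwhere(lab == comp)  # lexicographic order
        size = coords.shape[0]
        if size <= crit.min_cluster_size:
            continue
        vals = acc.values[tuple(coords.T)]
        vmax = vals.max()
        tied = np.flatnonzero(vals == vmax)
        if tied.size > 1:
            centroid = (coords * vals[:, None]).sum(axis=0) / vals.sum()
            d2 = ((coords[tied] - centroid) ** 2).sum(axis=1)
            peak_i = int(tied[np.argmin(d2)])  # argmin keeps lexicographic first
        else:
            peak_i = int(tied[0])
        peak = tuple(int(c) for c in coords[peak_i])
        world = affine @ np.array([*peak, 1.0])
        out_label += 1
        records.append(
            ClusterRecord(
                label=out_label,
                member_flat=np.ravel_multi_index(coords.T, acc.values.shape),
                peak_index=peak,
                peak_coord_world=tuple(float(w) for w in world[:3]),
                cluster_size=size,
                peak_accuracy=float(vals[peak_i]),
            )
        )
    records.sort(key=lambda r: r.peak_accuracy, reverse=True)
    for i, r in enumerate(records, start=1):
        r.label = i
    return records


def cluster_cv_accuracy(
    X: np.ndarray,
    labels,
    member_flat: np.ndarray,
    folds: FoldScheme,
    C: float = 1.0,
    scaling: str = "center",
) -> float:
    """Cross-validated accuracy using one cluster's voxels as the feature set."""
    y = _binary_labels(labels)
    Xc = X[:, member_flat]
    correct = 0
    total = 0
    with sklearn.config_context(assume_finite=True):
        for train, test in folds.folds:
            Xtr, Xte = _preprocess(Xc[train], Xc[test], scaling)
            a = _fit_accuracy(Xtr, y[train], Xte, y[test], C)
            correct += a * len(test)
            total += len(test)
    return correct / total


def permutation_test_cluster(
    cluster: ClusterRecord,
    maps: list[GreyMatterMap],
    labels,
    perm: PermutationSpec,
    n_folds: int = 10,
    C: float = 1.0,
) -> ClusterRecord:
    """Label-permutation inference on one surviving cluster.

    The observed statistic is the cross-validated accuracy over the
    cluster's voxels. For each resampling the group labels are permuted,
    a fresh balanced fold scheme is drawn, and the accuracy recomputed;
    the p-value uses the add-one estimator
    (1 + #{permuted >= observed}) / (n_resamplings + 1), which never
    returns 0. The record is updated in place and returned.
    """
    labels = np.asarray(labels)
    X = np.stack([m.values.reshape(-1) for m in maps])
    rng = np.random.default_rng(perm.seed)
    folds_obs = make_fold_scheme(labels, n_folds=n_folds, seed=perm.seed)
    observed = cluster_cv_accuracy(X, labels, cluster.member_flat, folds_obs, C)
    n_ge = 0
    for i in range(perm.n_resamplings):
        perm_labels = rng.permutation(labels)
        folds_i = make_fold_scheme(
            perm_labels, n_folds=n_folds, seed=int(rng.integers(0, 2**31 - 1))
        )
        a = cluster_cv_accuracy(X, perm_labels, cluster.member_flat, folds_i, C)
        if a >= observed:
            n_ge += 1
    cluster.perm_p = (1 + n_ge) / (perm.n_resamplings + 1)
    cluster.observed_accuracy = observed
    return cluster


def cluster_univariate_test(
    maps: list[GreyMatterMap], labels, cluster: ClusterRecord
) -> tuple[np.ndarray, TTestResult]:
    """Per-subject mean GM over the cluster, plus the pooled group t-test."""
    if cluster.member_flat.size == 0:
        raise ValueError("empty cluster")
    labels = np.asarray(labels)
    means = np.array(
        [m.values.reshape(-1)[cluster.member_flat].mean() for m in maps]
    )
    groups = np.unique(labels)
    res = pooled_ttest(means[labels == groups[0]], means[labels == groups[1]])
    return means, res


def correlate_with_behavior(x, score, method: str = "pearson") -> CorrelationResult:
    """Correlate per-subject values with the behavioural (TDI) score.

    Subjects with a missing score are dropped pairwise; df = n_pairs - 2.
    """
    return correlate(x, score, method=method)
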