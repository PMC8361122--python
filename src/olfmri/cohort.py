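"""Synthetic two-group cohorts with known ground truth.

The generator emulates the study conditions of a sensory-loss cohort: a
group with acquired smell loss (group A, n = 20) versus matched controls
(group B, n = 23), smooth modulated grey-matter maps with planted
multivoxel group-discriminative clusters, 96-ROI BOLD time series of 216
volumes at TR 2.3 s carrying intermittent inter-regional coupling that may
differ by group, bounded-random-walk realignment traces calibrated to the
groups' mean framewise displacement (0.162 vs 0.120 mm), and composite
olfactory (TDI) scores near the group means 13.35 and 35.21 (three
controls unscored). Every planted effect is returned as explicit ground
truth so each downstream analysis stage has a recovery test.

The odour-detection threshold instrument is also simulated: a
three-alternative forced-choice ascending staircase over a 16-step binary
dilution series, stopping after seven reversals, scored as the mean of the
last four reversal steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .mvpa import GreyMatterMap
from .prep import AcquisitionSpec, ROIAtlas, ROITimeSeriesMatrix, bandpass

__all__ = [
    "ClusterSpec",
    "CouplingSpec",
    "CohortConfig",
    "StaircaseConfig",
    "StaircaseResult",
    "OlfactoryScore",
    "SubjectRecord",
    "Cohort",
    "ellipsoid_mask",
    "generate_gm_cohort",
    "generate_roi_timeseries",
    "generate_motion_traces",
    "generate_atlas",
    "generate_olfactory_scores",
    "generate_cohort",
    "simulate_staircase",
    "tdi_score",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
SEED_CLASSES = ("APC", "PPC", "OFC")


@dataclass(frozen=True)
class ClusterSpec:
    """A planted spherical group effect in the grey-matter maps.

    ``effect_size`` is Cohen-d-like per voxel (in units of the
    post-smoothing voxel SD). ``mean_shift`` adds a uniform offset to
    group A inside the sphere; ``pattern`` adds a fixed random +/-1 sign
    pattern scaled by the effect size (multivoxel information with little
    univariate signal).
    """

    center_voxel: tuple[int, int, int]
    radius_vox: int
    effect_style: str = "pattern"
    effect_size: float = 3.0

    def __post_init__(self):
        if self.effect_style not in ("mean_shift", "pattern"):
            raise ValueError("effect_style must be 'mean_shift' or 'pattern'")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.radius_vox < 1:
            raise ValueError("radius_vox must be >= 1")

    def validate_grid(self, grid_shape):
        c = np.asarray(self.center_voxel)
        if np.any(c - self.radius_vox < 0) or np.any(
            c + self.radius_vox >= np.asarray(grid_shape)
        ):
            raise ValueError(f"planted sphere {self} extends outside grid {grid_shape}")

    def mask(self, grid_shape) -> np.ndarray:
        grids = np.indices(grid_shape)
        d2 = sum((g - c) ** 2 for g, c in zip(grids, self.center_voxel))
        return d2 <= self.radius_vox**2


@dataclass(frozen=True)
class CouplingSpec:
    """A planted intermittent coupling between two ROIs.

    During one contiguous burst covering ``burst_fraction`` of the record
    (uniform random onset per subject), the target shares a common
    component with the seed yielding within-burst correlation of about
    ``burst_corr``. ``group`` restricts the effect to one group or plants
    it in both.
    """

    seed_roi: int
    target_roi: int
    group: str = "both"
    burst_fraction: float = 0.5
    burst_corr: float = 0.9

    def __post_init__(self):
        if self.seed_roi == self.target_roi:
            raise ValueError("seed and target ROI must differ")
        if self.group not in ("A", "B", "both"):
            raise ValueError("group must be 'A', 'B' or 'both'")
        if not (0 <= self.burst_fraction <= 1):
            raise ValueError("burst_fraction must lie in [0, 1]")
        if not (0 < self.burst_corr < 1):
            raise ValueError("burst_corr must lie in (0, 1)")

    def applies_to(self, group: str) -> bool:
        return self.group in ("both", group)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for the synthetic cohort."""

    n_group_a: int = 20
    n_group_b: int = 23
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 3.0
    smoothing_fwhm_mm: float = 6.0
    planted_clusters: tuple[ClusterSpec, ...] = ()
    n_rois: int = 96
    n_volumes: int = 216
    tr_s: float = 2.3
    coupling_edges: tuple[CouplingSpec, ...] = ()
    tdi_mean_a: float = 13.35
    tdi_mean_b: float = 35.21
    tdi_sd_a: float = 2.24  # SEM 0.50 x sqrt(20)
    tdi_sd_b: float = 2.91  # SEM 0.65 x sqrt(20 scored controls)
    n_unscored_b: int = 3  # controls without behavioural scores
    fd_mean_a: float = 0.162
    fd_mean_b: float = 0.120
    seed: int = 0

    def __post_init__(self):
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("group sizes must be positive")
        if self.n_rois < 2 or self.n_rois % 2 != 0:
            raise ValueError("n_rois must be even (hemisphere-paired) and >= 2")
        if self.voxel_size_mm <= 0 or self.smoothing_fwhm_mm < 0:
            raise ValueError("voxel size must be positive, smoothing nonnegative")
        if not (0 <= self.tdi_mean_a <= 48 and 0 <= self.tdi_mean_b <= 48):
            raise ValueError("TDI means must lie in [0, 48]")
        if self.n_volumes < 5:
            raise ValueError("n_volumes must cover at least the shortest window")
        if self.n_unscored_b < 0 or self.n_unscored_b > self.n_group_b:
            raise ValueError("n_unscored_b out of range")
        for c in self.planted_clusters:
            c.validate_grid(self.grid_shape)
        for e in self.coupling_edges:
            if not (1 <= e.seed_roi <= self.n_rois and 1 <= e.target_roi <= self.n_rois):
                raise ValueError(f"coupling edge {e} references ROI outside 1..{self.n_rois}")

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    @property
    def group_labels(self) -> np.ndarray:
        return np.array(["A"] * self.n_group_a + ["B"] * self.n_group_b)

    @property
    def subject_ids(self) -> list[str]:
        return [
            f"sub-A{i + 1:02d}" for i in range(self.n_group_a)
        ] + [f"sub-B{i + 1:02d}" for i in range(self.n_group_b)]

    @property
    def acquisition(self) -> AcquisitionSpec:
        return AcquisitionSpec(tr_s=self.tr_s, n_volumes=self.n_volumes)

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size_mm * (np.asarray(self.grid_shape) - 1) / 2.0
        return aff


def _rngs(config: CohortConfig, n_streams: int = 6):
    """Independent per-artifact RNG streams so stages stay seed-isolated."""
    children = np.random.SeedSequence(config.seed).spawn(n_streams)
    return [np.random.default_rng(c) for c in children]


def ellipsoid_mask(grid_shape) -> np.ndarray:
    """Brain mask: an axis-aligned ellipsoid inscribed in the grid."""
    shape = np.asarray(grid_shape)
    center = (shape - 1) / 2.0
    semi = np.maximum(shape / 2.0 - 1.0, 1.0)
    grids = np.indices(grid_shape)
    d = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return d <= 1.0


def generate_gm_cohort(
    config: CohortConfig,
) -> tuple[list[GreyMatterMap], list[np.ndarray]]:
    """Smooth grey-matter maps with planted group-discriminative clusters.

    Background is truncated-Gaussian tissue density (mean 0.5, SD 0.1)
    smoothed at ``smoothing_fwhm_mm``; planted effects are added after
    smoothing, scaled by the empirical post-smoothing voxel SD so the
    per-voxel effect size is exactly the requested Cohen-d-like value.
    Values are clipped to >= 0. Returns the maps (group A first) and one
    boolean ground-truth mask per planted cluster.
    """
    rng_gm, rng_pattern, *_ = _rngs(config)
    shape = config.grid_shape
    sigma_vox = config.smoothing_fwhm_mm * FWHM_TO_SIGMA / config.voxel_size_mm
    mask = ellipsoid_mask(shape)
    affine = config.affine()

    raw = rng_gm.normal(0.5, 0.1, size=(config.n_subjects, *shape))
    np.clip(raw, 0.0, None, out=raw)
    if sigma_vox > 0:
        for s in range(config.n_subjects):
            raw[s] = ndimage.gaussian_filter(raw[s], sigma_vox)

    truth_masks: list[np.ndarray] = []
    is_a = config.group_labels == "A"
    for spec in config.planted_clusters:
        cmask = spec.mask(shape)
        truth_masks.append(cmask)
        vox = np.flatnonzero(cmask.reshape(-1))
        flat = raw.reshape(config.n_subjects, -1)
        sd_unit = float(np.mean(flat[:, vox].std(axis=0)))
        if spec.effect_style == "mean_shift":
            delta = np.full(vox.size, spec.effect_size * sd_unit)
        else:
            signs = rng_pattern.choice([-1.0, 1.0], size=vox.size)
            delta = spec.effect_size * sd_unit * signs
        flat[np.ix_(is_a, vox)] += delta

    np.clip(raw, 0.0, None, out=raw)
    maps = [
        GreyMatterMap(
            values=raw[s],
            voxel_size_mm=config.voxel_size_mm,
            affine=affine,
            brain_mask=mask,
        )
        for s in range(config.n_subjects)
    ]
    return maps, truth_masks


def generate_roi_timeseries(
    config: CohortConfig,
) -> tuple[list[ROITimeSeriesMatrix], list[dict]]:
    """Band-limited ROI time series with planted intermittent couplings.

    Baseline rows are white noise band-limited to the analysis band
    (0.01-0.1 Hz) and scaled to unit SD. For every coupling spec matching
    a subject's group, one contiguous burst of length
    round(burst_fraction * n_volumes) with a uniform random onset replaces
    the target's samples by a mixture sharing the seed's signal, giving
    within-burst correlation of about burst_corr. Ground truth lists each
    planted burst's subject, edge and interval.
    """
    _, _, rng_ts, *_ = _rngs(config)
    T = config.n_volumes
    acq = config.acquisition
    mats: list[ROITimeSeriesMatrix] = []
    truth: list[dict] = []
    roi_labels = np.arange(1, config.n_rois + 1)
    for sid, group in zip(config.subject_ids, config.group_labels):
        data = bandpass(rng_ts.normal(size=(config.n_rois, T)), acq)
        sd = data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data /= sd
        for edge in config.coupling_edges:
            if not edge.applies_to(group):
                continue
            L = int(round(edge.burst_fraction * T))
            if L == 0:
                continue
            start = int(rng_ts.integers(0, T - L + 1))
            sl = slice(start, start + L)
            s_row = data[edge.seed_roi - 1]
            t_row = data[edge.target_roi - 1]
            c = edge.burst_corr
            t_row[sl] = c * s_row[sl] + np.sqrt(1 - c * c) * t_row[sl]
            truth.append(
                {
                    "subject_id": sid,
                    "seed_roi": int(edge.seed_roi),
                    "target_roi": int(edge.target_roi),
                    "start": start,
                    "stop": start + L,
                    "burst_corr": c,
                    "burst_fraction": edge.burst_fraction,
                }
            )
        mats.append(
            ROITimeSeriesMatrix(data=data, roi_labels=roi_labels, subject_id=sid)
        )
    return mats, truth


def generate_motion_traces(
    config: CohortConfig, walk_bound_mm: float = 2.0
) -> list[np.ndarray]:
    """Bounded random-walk realignment traces (3 translations, 3 rotations).

    Step scales are calibrated so the expected mean framewise displacement
    matches the group targets (translations and rotations contribute
    equally; E|N(0,s)| = s*sqrt(2/pi)). The walk is clipped to
    +/-``walk_bound_mm`` (rotations to the arc-equivalent bound).
    """
    *_, rng_mot, _, _ = _rngs(config)
    T = config.n_volumes
    head_radius = 50.0
    traces = []
    for group in config.group_labels:
        target = config.fd_mean_a if group == "A" else config.fd_mean_b
        s_t = target / (6.0 * np.sqrt(2.0 / np.pi))
        s_r = s_t / head_radius
        steps = rng_mot.normal(size=(T, 6)) * np.array([s_t] * 3 + [s_r] * 3)
        steps[0] = 0.0
        walk = np.cumsum(steps, axis=0)
        bound = np.array([walk_bound_mm] * 3 + [walk_bound_mm / head_radius] * 3)
        traces.append(np.clip(walk, -bound, bound))
    return traces


def generate_atlas(config: CohortConfig) -> ROIAtlas:
    """Mirror-paired integer-label parcellation of the brain mask.

    The left half of the mask is partitioned into n_rois/2 equal-count
    parcels (lexicographic chunking); the right hemisphere is its exact
    x-flip, so flipping x maps every label onto its partner. The first
    three pairs are flagged as the olfactory seed ROIs (APC, PPC, OFC
    analogues).
    """
    shape = config.grid_shape
    mask = ellipsoid_mask(shape)
    nx = shape[0]
    half = config.n_rois // 2
    left = np.argwhere(mask[: nx // 2])
    if left.shape[0] < half:
        raise ValueError(
            f"grid {shape} too small for {config.n_rois} ROIs ({left.shape[0]} left voxels)"
        )
    labels = np.zeros(shape, dtype=np.int16)
    chunks = np.array_split(np.arange(left.shape[0]), half)
    for lab0, chunk in enumerate(chunks):
        for i, j, k in left[chunk]:
            labels[i, j, k] = lab0 + 1
            labels[nx - 1 - i, j, k] = lab0 + 1 + half
    rows = []
    for lab0 in range(half):
        seed_class = SEED_CLASSES[lab0] if lab0 < len(SEED_CLASSES) else "none"
        name = seed_class if seed_class != "none" else f"roi{lab0 + 1:03d}"
        for hemi, lab in (("L", lab0 + 1), ("R", lab0 + 1 + half)):
            rows.append(
                {
                    "label": lab,
                    "name": name,
                    "hemisphere": hemi,
                    "partner_label": lab + half if hemi == "L" else lab - half,
                    "is_seed": seed_class != "none",
                    "seed_class": seed_class,
                }
            )
    meta = pd.DataFrame(rows).sort_values("label").reset_index(drop=True)
    return ROIAtlas(labels=labels, meta=meta, affine=config.affine())


@dataclass(frozen=True)
class OlfactoryScore:
    """Composite Sniffin'-Sticks-style score: T + D + I, each 0-16, max 48."""

    threshold: float
    discrimination: int
    identification: int
    tdi: float

    def __post_init__(self):
        for name in ("threshold", "discrimination", "identification"):
            v = getattr(self, name)
            if not (0 <= v <= 16):
                raise ValueError(f"{name}={v} outside [0, 16]")
        expected = self.threshold + self.discrimination + self.identification
        if abs(self.tdi - expected) > 1e-12 or self.tdi > 48:
            raise ValueError("tdi must equal the component sum (max 48)")


def tdi_score(threshold: float, discrimination: int, identification: int) -> OlfactoryScore:
    """Compose the global olfactory score as the sum of the three subtests."""
    if int(discrimination) != discrimination or int(identification) != identification:
        raise ValueError("discrimination and identification are integer scores")
    return OlfactoryScore(
        threshold=float(threshold),
        discrimination=int(discrimination),
        identification=int(identification),
        tdi=float(threshold) + int(discrimination) + int(identification),
    )


@dataclass(frozen=True)
class StaircaseConfig:
    """Adaptive 3-AFC ascending staircase over a 16-step dilution series.

    Steps are numbered so that a higher step means a stronger (easier)
    concentration: the simulated observer detects (probability 1 - lapse)
    whenever the presented step >= ``true_threshold_step``, and guesses at
    1/n_alternatives otherwise.
    """

    n_steps: int = 16
    n_alternatives: int = 3
    n_reversals_stop: int = 7
    n_reversals_scored: int = 4
    true_threshold_step: float = 8.0
    lapse_rate: float = 0.0
    max_trials: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_reversals_scored > self.n_reversals_stop:
            raise ValueError("cannot score more reversals than are collected")
        if not (1 <= self.true_threshold_step <= self.n_steps):
            raise ValueError("true threshold must lie within the dilution series")
        if not (0 <= self.lapse_rate < 1):
            raise ValueError("lapse rate must lie in [0, 1)")


@dataclass
class StaircaseResult:
    trials: pd.DataFrame  # trial, step, correct, reversal
    reversal_steps: list[int]
    threshold: float | None
    complete: bool


def simulate_staircase(sc: StaircaseConfig) -> StaircaseResult:
    """Run the staircase: up on any miss, down after two successive hits.

    A reversal is a change of movement direction; the run stops after
    ``n_reversals_stop`` reversals and the threshold score is the
    arithmetic mean of the last ``n_reversals_scored`` reversal steps. If
    the trial budget is exhausted first the run is flagged incomplete and
    the score is absent.
    """
    rng = np.random.default_rng(sc.seed)
    step = 1
    direction = +1  # ascending start
    consecutive = 0
    reversals: list[int] = []
    log = []
    for trial in range(sc.max_trials):
        if step >= sc.true_threshold_step:
            correct = bool(rng.random() < 1.0 - sc.lapse_rate)
        else:
            correct = bool(rng.random() < 1.0 / sc.n_alternatives)
        consecutive = consecutive + 1 if correct else 0
        move = 0
        if not correct:
            move = +1
        elif consecutive >= 2:
            move = -1
            consecutive = 0
        reversed_here = move != 0 and move != direction
        if reversed_here:
            reversals.append(step)
        log.append(
            {"trial": trial, "step": step, "correct": correct, "reversal": reversed_here}
        )
        if len(reversals) >= sc.n_reversals_stop:
            break
        if move != 0:
            direction = move
            step = int(np.clip(step + move, 1, sc.n_steps))
    complete = len(reversals) >= sc.n_reversals_stop
    threshold = (
        float(np.mean(reversals[-sc.n_reversals_scored :])) if complete else None
    )
    return StaircaseResult(
        trials=pd.DataFrame(log),
        reversal_steps=reversals,
        threshold=threshold,
        complete=complete,
    )


def generate_olfactory_scores(config: CohortConfig) -> list[OlfactoryScore | None]:
    """TDI scores near the group means; the last controls may be unscored.

    The per-subject target TDI is drawn from the group's normal
    distribution and split into the three subtests (threshold in quarter
    steps, the mean of four reversal points; discrimination and
    identification as integers), preserving the exact component sum.
    """
    *_, rng_beh, _ = _rngs(config)
    scores: list[OlfactoryScore | None] = []
    n_scored_b = config.n_group_b - config.n_unscored_b
    for i, group in enumerate(config.group_labels):
        if group == "B" and (i - config.n_group_a) >= n_scored_b:
            scores.append(None)
            rng_beh.normal(size=3)  # keep the stream aligned
            continue
        mean = config.tdi_mean_a if group == "A" else config.tdi_mean_b
        sd = config.tdi_sd_a if group == "A" else config.tdi_sd_b
        z = rng_beh.normal(size=3)
        target = float(np.clip(mean + sd * z[0], 0.5, 47.5))
        base = target / 3.0
        disc = int(np.clip(round(base + z[1]), 0, 16))
        ident = int(np.clip(round(base + z[2]), 0, 16))
        thr = float(np.clip(round((target - disc - ident) * 4) / 4.0, 0, 16))
        scores.append(tdi_score(thr, disc, ident))
    return scores


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    gm_map: GreyMatterMap | None = None
    roi_ts: ROITimeSeriesMatrix | None = None
    motion: np.ndarray | None = None
    olfactory: OlfactoryScore | None = None

    def __post_init__(self):
        if self.group not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")


@dataclass
class Cohort:
    """A complete synthetic cohort plus all planted ground truth."""

    config: CohortConfig
    subjects: list[SubjectRecord]
    atlas: ROIAtlas
    gm_truth_masks: list[np.ndarray]
    coupling_truth: list[dict]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def gm_maps(self) -> list[GreyMatterMap]:
        return [s.gm_map for s in self.subjects]

    @property
    def timeseries(self) -> list[ROITimeSeriesMatrix]:
        return [s.roi_ts for s in self.subjects]

    def tdi(self) -> np.ndarray:
        return np.array(
            [s.olfactory.tdi if s.olfactory is not None else np.nan for s in self.subjects]
        )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate every per-subject artifact for one seeded cohort."""
    maps, truth_masks = generate_gm_cohort(config)
    ts, coupling_truth = generate_roi_timeseries(config)
    motion = generate_motion_traces(config)
    scores = generate_olfactory_scores(config)
    atlas = generate_atlas(config)
    subjects = [
        SubjectRecord(
            subject_id=sid,
            group=grp,
            gm_map=m,
            roi_ts=t,
            motion=mo,
            olfactory=sc,
        )
        for sid, grp, m, t, mo, sc in zip(
            config.subject_ids, config.group_labels, maps, ts, motion, scores
        )
    ]
    return Cohort(
        config=config,
        subjects=subjects,
        atlas=atlas,
        gm_truth_masks=truth_masks,
        coupling_truth=coupling_truth,
    )
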