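# Methods

`olfmri` implements two group-level analyses of sensory-loss
neuroplasticity — searchlight classification of grey-matter (GM) volume and
fractional dynamic functional connectivity (dFC) of resting-state BOLD —
together with the behavioural score model of the Sniffin' Sticks olfactory
battery and a synthetic-cohort generator that makes every stage testable
against planted ground truth. This note records the models, their
assumptions, the defaults, and the numerical choices made where the design
was genuinely open.

## Study design encoded in the defaults

The default configuration is a two-group resting-state morphometry study:
group A (acquired smell loss, n = 20) versus group B (matched controls,
n = 23); 96 hemisphere-paired ROIs (90 whole-brain parcels plus 6
hand-drawn olfactory seeds: anterior piriform APC, posterior piriform PPC
and olfactory orbitofrontal OFC, left and right); 216 functional volumes at
TR 2.3 s band-passed to 0.01–0.1 Hz; composite olfactory score
TDI = Threshold + Discrimination + Identification, each subtest 0–16, so
TDI ∈ [0, 48], with group means 13.35 (A) and 35.21 (B) and three controls
unscored. All two-sample contrasts at these group sizes have
df = 20 + 23 − 2 = 41.

## Searchlight morphometry MVPA

Per-subject modulated GM volume maps on a common grid are scanned with a
spherical searchlight of radius 6 mm (all in-mask voxels whose
centre-to-centre world distance from the centre voxel is ≤ 6 mm; on a 2 mm
isotropic grid a full sphere has 123 voxels). At every centre a linear
max-margin classifier (liblinear squared-hinge SVM, C = 1, the model of
`sklearn.svm.LinearSVC`) is trained to separate the groups from the
sphere's voxel values under a balanced cross-validation: each of 10 folds
trains on 19 subjects per group (the larger group is semi-randomly
subsampled) and tests on one held-out subject from each group; every
subject enters at least one training set, enforced by a deterministic
fix-up. Mean test accuracy across folds is written to the centre voxel
(centres only, no sphere-overlap averaging).

Supra-threshold voxels (accuracy strictly > 0.70) are grouped into
26-connected components; components strictly larger than 100 voxels
survive. Each surviving cluster receives a label-permutation p-value: the
observed statistic is the cross-validated accuracy over the cluster's
voxels, and for each of 5000 resamplings the group labels are permuted, a
fresh balanced fold scheme drawn, and the accuracy recomputed. The p-value
is the add-one estimator (1 + #{permuted ≥ observed}) / (n + 1), which is
never zero and is uniform under the null (verified by a
Kolmogorov–Smirnov calibration test over 100 simulated null cohorts).

Follow-ups on surviving clusters: a pooled-variance two-sample t-test on
per-subject mean GM over the cluster (df = n1 + n2 − 2, two-sided p, 95 %
CI of the A − B mean difference) and Pearson or Spearman correlation of
cluster GM with the TDI score, dropping unscored subjects pairwise
(df = n_pairs − 2). p-values are always two-sided; the pipeline emits a
warning when a contrast lands in [0.05, 0.06), where a one-sided reading
would flip the significance call.

Numerical choices:

- **Feature conditioning.** Sphere features are mean-centred with
  training-fold means and divided by one global scalar (the pooled
  training SD). Raw modulated GM (offset ≈ 0.5, post-smoothing voxel SD
  ≈ 1e-2) is so badly scaled that the solver fails to converge within its
  iteration budget; centring preserves the multivoxel pattern and uses no
  test-set information. Full per-feature z-scoring and raw values remain
  options.
- **Degenerate spheres.** If every training feature is constant the sphere
  carries no information and its accuracy is defined as chance (0.5).
- **Peak ties.** With strong effects the accuracy map saturates at 1.0
  over a halo wider than the informative region. Among tied maximal
  voxels the peak is the one nearest the accuracy-weighted centroid of the
  component (residual ties: lexicographic grid order) — deterministic and
  centre-seeking, so the reported peak is scientifically meaningful.
- **Solver.** The classifier is invoked through liblinear's solver entry
  point (primal when samples outnumber features, dual otherwise, seed
  fixed); a unit test asserts exact prediction agreement with the public
  `LinearSVC` estimator. This matters because the permutation calibration
  performs ~3·10^5 fits.

## Time-series preparation

Framewise displacement follows the Power formulation:
FD_t = Σ|Δ translations| + r·Σ|Δ rotations| with head radius r = 50 mm
(configurable), FD_1 = 0 by convention. Group motion is compared by a
pooled t-test on subject mean FD. The band-pass is a zero-phase 4th-order
Butterworth (0.01–0.1 Hz) applied forward–backward with odd-reflection
padding; pass-band amplitude is preserved within 5 % and repeated
filtering changes a steady-state pass-band signal by well under 1 % RMS
(edge transients from the 0.01 Hz skirt ring for ~40 samples and are
excluded from that check). ROI signals are voxel means per atlas label,
band-passed after averaging (averaging and linear filtering commute, so
the order is conventional); empty labels propagate as missing rows, never
as zeros. FD nuisance regression is per-ROI OLS on [intercept, FD],
applied to the ROI BOLD series before windowing (a config switch defers it
to the dFC level); residuals are orthogonal to FD to numerical precision,
and constant FD degenerates to demeaning.

## Fractional dynamic connectivity

For a seed–target pair, Pearson correlations are computed in sliding
windows (slide step 1 TR) for every width in the grid 5, 7, …, 59 TRs.
The grid reading deserves a note: the width range "5 to 60 in steps of 2"
is unreachable at 60, so the grid tops out at 59; the step is interpreted
as the increment over *widths*, with the slide along time fixed at 1 TR
(both configurable). A window counts as connected when r strictly exceeds
the critical value 0.64 — the two-tailed critical Pearson correlation at
α = 0.001 with df = 21 (t-inversion r = t/√(t² + df); the df calibration
that reproduces the printed threshold exactly). Thresholding the
Fisher-z-transformed series at atanh(0.64) selects the identical window
set, and anticorrelations never count. The fractional connectivity is the
fraction of defined windows above threshold (windows with zero variance
are undefined and excluded from numerator and denominator alike, and
counted in a QC field), averaged unweighted over window widths, computed
within each hemisphere (left seed → left target, right seed → right
target) and then averaged across hemispheres.

Group contrasts are pooled t-tests per seed class (APC, PPC, OFC by
default; any ROI pair can be declared a seed) against every other
hemisphere pair, reported uncorrected and sorted by |t| — mirroring the
analysed design, which reports uncorrected p at a conservative
single-window threshold; an optional Benjamini–Hochberg column is off by
default. The brain–behaviour link is a Spearman correlation (midranks for
ties) between one edge's per-subject fractions and TDI.

## Synthetic cohort generator

The generator's role is recovery testing: every planted effect is returned
as machine-readable ground truth.

- **GM maps**: truncated-Gaussian tissue density (mean 0.5, SD 0.1)
  smoothed with a Gaussian kernel (FWHM 6 mm default). Group effects are
  planted *after* smoothing, scaled by the empirical post-smoothing voxel
  SD, so the per-voxel effect size is exactly the requested Cohen-d-like
  value (smoothing a ±1 sign pattern would otherwise annihilate it).
  `mean_shift` adds a uniform offset to group A inside a sphere;
  `pattern` adds a fixed random sign pattern — multivoxel information
  with weak univariate signal. Values are clipped to ≥ 0. What this does
  not emulate: anatomical covariance structure, segmentation artefacts,
  registration error; a pass on synthetic maps validates the machinery,
  not real-data effect sizes.
- **ROI time series**: white noise band-limited to 0.01–0.1 Hz, unit SD
  per row, keeping the generator consistent with the analysis band. Each
  coupling spec plants one contiguous burst (uniform random onset)
  covering `burst_fraction` of the record in which the target shares the
  seed's signal at mixing weight `burst_corr`; a single segment keeps the
  ground-truth dwell fraction exact. Real BOLD autocorrelation beyond the
  band limit, physiological noise and spatial leakage are not modelled.
- **Motion**: bounded Gaussian random walks over the six rigid-body
  parameters, step SD calibrated analytically (E|N(0,s)| = s√(2/π),
  translations and rotations contributing equally) so expected mean FD
  hits the group targets 0.162 / 0.120 mm.
- **Behaviour**: per-subject TDI targets drawn from the group normal
  distributions (SDs back-computed from the reported SEMs), decomposed
  into integer discrimination/identification and a quarter-step threshold
  so the component sum is exact; the last three controls are unscored.
- **Staircase**: 3-alternative forced-choice ascending staircase over a
  16-step dilution series (higher step = stronger concentration). The
  observer detects with probability 1 − lapse at steps ≥ the true
  threshold and guesses at 1/3 below it. Two successive correct responses
  step down, any incorrect steps up; a direction change is a reversal; the
  run stops at 7 reversals and the score is the mean of the last 4
  reversal steps. This rule equilibrates at the 70.7 % point, so the score
  sits systematically just below a step-function observer's threshold
  (mean bias ≈ −0.85 steps at threshold 8); the recovery requirement is
  absolute bias < 1 dilution step, which holds for lapse ≤ 0.05.
- **Atlas**: the left half of the ellipsoidal brain mask is chunked into
  n_rois/2 equal-count parcels and mirrored exactly by x-flip, so
  hemisphere partnership is an involution by construction; the first
  three pairs are flagged APC/PPC/OFC.

Per-artifact RNG streams are spawned from one master seed, so (for
example) changing nothing re-generates bit-identical cohorts, and the
connectivity stage's seed never perturbs the morphometry stage.

## Validation scales

The test suite validates calibration and recovery at reduced problem
sizes chosen to keep a full run on one CPU comfortably short while leaving
the statistical checks well-powered: chance/permutation calibration on
12³-voxel null cohorts (100 cohorts × 200 resamplings for the uniformity
KS test at α = 0.01); morphometry recovery on 20 seeded 14³ cohorts
(planted pattern d = 3, 20+20 subjects, 500 resamplings, detection
required in ≥ 90 %); connectivity recovery on 20 cohorts of 16 ROIs × 120
volumes; the independence null against a ~10^5-draw Monte-Carlo oracle;
staircase recovery over 1000 seeds. The full-scale defaults (whole-grid
maps, 5000 resamplings, 96 ROIs, 216 volumes) are what the pipeline runs
when invoked on real-sized data.

## Known limitations

- The generator's noise model is spatially white before smoothing and
  temporally band-limited white; real GM maps and BOLD have richer
  covariance. Recovery rates on synthetic data are therefore optimistic
  relative to real data at matched effect sizes.
- Fold subsampling of the larger group means per-fold training sets are
  not unique; results at full scale carry the fold-scheme seed in the run
  manifest for exact reproducibility.
- Cluster anatomical labelling is user-supplied; no reference atlas
  lookup is performed.
- The dFC group tests are uncorrected by design (mirroring the analysed
  protocol); the optional FDR column should be used when the seed/target
  family grows beyond the design's ~47 tests.
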