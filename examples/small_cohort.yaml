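# Reduced-scale demonstration cohort: one planted morphometry cluster
# (multivoxel pattern, d = 4) and one group-A-only connectivity edge per
# hemisphere. The full-scale study profile is simply `olfmri all` with no
# overrides (20 vs 23 subjects, 24x28x24 grid, 96 ROIs, 216 volumes,
# 5000 resamplings).
cohort:
  n_group_a: 8
  n_group_b: 8
  grid_shape: [12, 14, 12]
  voxel_size_mm: 3.0
  smoothing_fwhm_mm: 6.0
  n_rois: 10
  n_volumes: 120
  n_unscored_b: 0
  planted_clusters:
    - {center_voxel: [6, 7, 6], radius_vox: 2, effect_style: pattern, effect_size: 4.0}
  coupling_edges:
    - {seed_roi: 2, target_roi: 4, group: A, burst_fraction: 0.5, burst_corr: 0.9}
    - {seed_roi: 7, target_roi: 9, group: A, burst_fraction: 0.5, burst_corr: 0.9}
cluster_criteria:
  acc_threshold: 0.70
  min_cluster_size: 20
permutation:
  n_resamplings: 50
window_grid:
  widths_tr: [5, 9, 13, 17, 21]
n_folds: 6
seed_classes: [PPC]
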