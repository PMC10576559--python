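seed: 3
output_dir: runs/demo
phantom:
  n_glioma: 12
  n_mets: 12
  grid_shape:
  - 48
  - 48
  - 40
  spacing_mm:
  - 1.0
  - 1.0
  - 1.0
  split_fractions:
  - 0.5
  - 0.25
  - 0.25
  noise_sd: 5.0
  glioma_radius_mm:
  - 5.0
  - 8.0
  mets_radius_mm:
  - 3.0
  - 5.0
  glioma_lesion_counts:
  - 1
  - 1
  - 1
  - 1
  - 2
  mets_lesion_counts:
  - 1
  - 2
  - 3
  - 4
preprocess:
  target_spacing_mm:
  - 1.0
  - 1.0
  - 1.0
roi:
  min_voxels: 50
  connectivity: 26
features:
  log_sigmas_mm:
  - 3.0
  - 5.0
  wavelet_family: coif1
  bin_width: 0.25
  gray_level_cap: null
selection:
  alpha: 0.05
  method: lasso
  top_n: 20
  n_keep: 20
model:
  folds: 3
  kinds:
  - gnb
  - logreg_l1
  - random_forest
  weight_grid:
  - - 1
    - 1
  - - 2
    - 1
  - - 2
    - 3
  - - 4
    - 3
  - - 3
    - 1
edpk:
  enabled: true
  set_number: 3
  min_voxels: 50
  weight_high:
  - 2.0
  - 1.0
  target_dice: 0.85
  high_regime_fusion: mean_of_masks
explain:
  enabled: true
  n_permutations: 50
  top_k: 20
  max_background: 100
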