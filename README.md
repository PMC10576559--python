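# gliomets

Computer-aided differentiation of **high-grade gliomas** from **brain
metastases (mets)** on two conventional MRI sequences (contrast-enhanced
T1 and T2-FLAIR), built as a tested, fully seedable pipeline that runs
end-to-end on synthetic 3D tumor phantoms.

The two tumor types call for different treatment, and they differ in ways
quantitative imaging can capture: gliomas are usually a single large,
irregular lesion with enhancing, necrotic and edematous compartments,
while mets frequently present as several smaller enhancing lesions.  The
pipeline turns each case into a high-dimensional radiomics vector and
classifies it with a weighted soft-voting ensemble, with a decision layer
that adapts to automatic (imperfect) segmentations.

## What the package computes

* **Phantoms** — class-conditional synthetic cases: two co-registered
  intensity channels, ground-truth compartment masks (0 background,
  1 edema, 2 enhancing, 3 necrotic), and a mask-corruption operator that
  emulates automatic segmentation at a controllable Dice coefficient.
* **Radiomics** — per sequence, exactly **960 features**: 14 shape + 18
  first-order and 68 texture features (GLCM 22, GLDM 14, GLRLM 16,
  GLSZM 16) on each of 11 image types (original, Laplacian-of-Gaussian at
  σ = 3 and 5 mm, 8 one-level 3D wavelet subbands).  Two sequences plus
  the lesion number give a 1921-long case vector.
* **Selection** — Mann–Whitney prefilter (p < 0.05), then LASSO, mutual
  information, or recursive feature elimination with a random forest;
  Pearson correlation matrices of the survivors.
* **RSV model** — soft vote of the two best base classifiers (out of
  Gaussian naive Bayes, L1 logistic regression, polynomial/RBF SVM,
  random forest, gradient-boosted trees) with weight pair ω = (ω₁, ω₂)
  chosen from {1:1, 2:1, 2:3, 4:3, 3:1}; hyperparameters by grid search
  under the one-standard-deviation rule in stratified 10-fold CV.
* **EDPK** — ensemble decision strategy based on prior knowledge: after
  removing small false-positive components from the two automatic masks,
  `Number = max(L_G, L_M)` selects the branch.  `Number < 3`: merge the
  masks into one ROI, equal weights.  Otherwise: keep both masks,
  classify each, switch to the high-multiplicity weights (2:1) and
  average the votes.
* **Explanations** — additive Shapley attributions
  (y = y_base + Σ_j φ_j) of the ensemble probability, exact by coalition
  enumeration for ≤ 12 features and by seeded Monte-Carlo permutation
  sampling otherwise; cohort importance = mean |φ| per feature.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

```python
from gliomets.pipeline import run_all
from gliomets.presets import edpk_comparison_config

result = run_all(edpk_comparison_config(seed=2))
print("truth ACC/AUC", result.metrics_rsv_truth.acc, result.metrics_rsv_truth.auc)
print("fixed ACC/AUC", result.metrics_rsv_auto.acc, result.metrics_rsv_auto.auc)
print("edpk  ACC/AUC", result.metrics_edpk.acc, result.metrics_edpk.auc)
print(result.auto_probs.round(3).head(8).to_string())
```

On this 60-case cohort (30 gliomas, 30 mets, automatic masks degraded to
Dice ≈ 0.85) the run takes a couple of minutes and prints:

```
truth ACC/AUC 1.0 1.0
fixed ACC/AUC 1.0 1.0
edpk  ACC/AUC 1.0 1.0
            case_id  label  edpk_prob  fixed_prob
0   case0001-glioma      0      0.028       0.028
1   case0003-glioma      0      0.020       0.020
2   case0004-glioma      0      0.020       0.020
3   case0005-glioma      0      0.024       0.024
4   case0008-glioma      0      0.026       0.026
5   case0021-glioma      0      0.047       0.047
6     case0033-mets      1      0.958       0.958
7     case0038-mets      1      0.980       0.971
```

The phantom classes are deliberately separable (multiplicity, size, and
necrosis contrast all differ), so both pipelines classify the test split
perfectly here; on high-multiplicity cases the EDPK branch sharpens the
mets probabilities relative to the fixed-weight vote (rows 7+).  A much
smaller smoke cohort is available as `demo_config` — note that with only
a dozen training cases its selected features do not generalize to the
corrupted masks, which is the expected failure mode at toy scale.  The
same flow from a shell:

```bash
gliomets run-all --config configs/demo.yaml
gliomets simulate --n-glioma 20 --n-mets 20 --seed 7 --out runs/cohort
```

Every run writes a self-describing artifact directory (config snapshot,
manifest, feature CSV, selection/metrics/decision JSON, SHAP exports).

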