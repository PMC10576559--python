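"""End-to-end orchestration: simulate -> preprocess -> extract -> select ->
train -> (EDPK) predict -> evaluate -> explain.

``run_all`` executes the whole workflow on a synthetic cohort and returns a
:class:`RunResult`; every random choice derives from the single config seed,
so two runs with the same config are bit-identical.  Artifacts (feature
CSVs, selection JSON, metrics JSON, decision records, SHAP exports, config
snapshot, log) are written under the configured output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .edpk import EDPKConfig, PredictionRecord, edpk_predict
from .ensemble import ClassifierSpec, MetricsReport, RSVModel, build_rsv, evaluate
from .explain import ImportanceRanking, explain_cohort, importance_rank
from .featsel import (
    ScalerState,
    SelectionResult,
    fit_apply_scaler,
    lasso_select,
    mi_select,
    mwu_prefilter,
    pearson_matrix,
    rfe_rf_select,
)
from .imgproc import brain_mask_of, resample_isotropic, resample_mask, znorm_image
from .phantom import (
    CaseRecord,
    CohortRanges,
    corrupt_mask,
    generate_cohort,
    mets_style_mask,
)
from .radiomics import FeatureRegistry, FilterConfig, extract_case
from .roi import count_lesions, merge_masks, remove_small_lesions, whole_roi
from .volume import SegMask, Volume

logger = logging.getLogger(__name__)


def preprocess_case(case: CaseRecord, target_spacing=(1.0, 1.0, 1.0)) -> CaseRecord:
    """Resample to the target spacing (if needed) and Z-score normalize."""
    t1, fl, mask = case.t1ce, case.t2flair, case.truth_mask
    if not np.allclose(t1.spacing, target_spacing):
        t1 = resample_isotropic(t1, target_spacing, "linear")
        fl = resample_isotropic(fl, target_spacing, "linear")
        mask = resample_mask(mask, target_spacing)
    t1 = znorm_image(t1, brain_mask_of(t1))
    fl = znorm_image(fl, brain_mask_of(fl))
    return CaseRecord(
        case_id=case.case_id, t1ce=t1, t2flair=fl, truth_mask=mask,
        label=case.label, lesion_count_truth=case.lesion_count_truth,
    )


def extract_table(
    cases: list[CaseRecord],
    registry: FeatureRegistry,
    config: FilterConfig,
) -> pd.DataFrame:
    """Feature table (rows = cases) from the ground-truth ROI of each case."""
    rows = {}
    for case in cases:
        roi = whole_roi(case.truth_mask)
        rows[case.case_id] = extract_case(
            case.t1ce, case.t2flair, roi, case.lesion_count_truth,
            registry=registry, config=config,
        )
    return pd.DataFrame(rows).T


def select_features(
    scaled: pd.DataFrame,
    labels: np.ndarray,
    method: str,
    alpha: float = 0.05,
    top_n: int = 20,
    n_keep: int = 20,
    seed: int = 0,
) -> tuple[list[str], dict[str, SelectionResult]]:
    """Mann-Whitney prefilter followed by the configured selector chain."""
    results: dict[str, SelectionResult] = {}
    mwu = mwu_prefilter(scaled, labels, alpha=alpha)
    results["mwu"] = mwu
    current = mwu.kept_features or list(scaled.columns)

    for step in method.split("+"):
        sub = scaled[current]
        if step == "lasso":
            res = lasso_select(sub, labels, seed=seed)
        elif step == "mi":
            res = mi_select(sub, labels, top_n=top_n, seed=seed)
        elif step == "rfe_rf":
            res = rfe_rf_select(sub, labels, n_keep=n_keep, seed=seed)
        else:
            raise ValueError(f"unknown selection step {step!r}")
        results[step] = res
        if res.kept_features:
            current = res.kept_features
        else:
            logger.warning("selector %s kept nothing; keeping previous set", step)
    return current, results


@dataclass
class RunResult:
    config: PipelineConfig
    manifest: pd.DataFrame
    features: pd.DataFrame
    selected_features: list[str]
    selection: dict[str, SelectionResult]
    scaler: ScalerState
    rsv: RSVModel
    metrics_rsv_truth: MetricsReport
    metrics_rsv_auto: MetricsReport | None = None
    metrics_edpk: MetricsReport | None = None
    edpk_records: list[PredictionRecord] = field(default_factory=list)
    auto_probs: pd.DataFrame | None = None
    importance: ImportanceRanking | None = None
    timings: dict[str, float] = field(default_factory=dict)


def _fixed_rsv_predict_auto(
    case: CaseRecord,
    mask_g: SegMask,
    mask_m: SegMask,
    rsv: RSVModel,
    scaler: ScalerState,
    selected: list[str],
    registry: FeatureRegistry,
    fcfg: FilterConfig,
    min_voxels: int,
    reuse_record: "PredictionRecord | None" = None,
) -> float:
    """Non-adaptive baseline: one merged automatic ROI, fixed vote weights.

    In the low EDPK regime the merged ROI coincides with the EDPK one, so
    the already-extracted vector is reused (only the lesion-number column
    can differ).
    """
    merged = merge_masks(
        remove_small_lesions(mask_g, min_voxels), remove_small_lesions(mask_m, min_voxels)
    )
    roi = whole_roi(merged)
    if not roi.any():
        roi = whole_roi(case.truth_mask)  # degenerate corruption: fall back
    n_lesions = count_lesions(roi).lesion_count
    if (
        reuse_record is not None
        and reuse_record.decision.regime == "low"
        and reuse_record.features
    ):
        vec = reuse_record.features[0].copy()
        vec["lesion_number"] = float(n_lesions)
    else:
        vec = extract_case(
            case.t1ce, case.t2flair, roi, n_lesions, registry=registry, config=fcfg
        )
    scaled = scaler.transform(pd.DataFrame([vec]))[selected]
    return float(rsv.predict_proba(scaled)[0])


def run_all(cfg: PipelineConfig) -> RunResult:
    timings: dict[str, float] = {}
    t0 = time.time()

    ranges = CohortRanges(
        glioma_radius_mm=cfg.phantom.glioma_radius_mm,
        mets_radius_mm=cfg.phantom.mets_radius_mm,
        glioma_lesion_counts=cfg.phantom.glioma_lesion_counts,
        mets_lesion_counts=cfg.phantom.mets_lesion_counts,
        noise_sd=cfg.phantom.noise_sd,
    )
    cases, manifest = generate_cohort(
        cfg.phantom.n_glioma, cfg.phantom.n_mets, spec_ranges=ranges,
        seed=cfg.seed, grid_shape=cfg.phantom.grid_shape,
        spacing_mm=cfg.phantom.spacing_mm,
        split_fractions=cfg.phantom.split_fractions,
    )
    timings["simulate"] = time.time() - t0

    t0 = time.time()
    cases = [preprocess_case(c, cfg.preprocess.target_spacing_mm) for c in cases]
    timings["preprocess"] = time.time() - t0

    registry = FeatureRegistry(log_sigmas_mm=cfg.features.log_sigmas_mm)
    fcfg = FilterConfig(
        log_sigmas_mm=cfg.features.log_sigmas_mm,
        wavelet_family=cfg.features.wavelet_family,
        bin_width=cfg.features.bin_width,
        gray_level_cap=cfg.features.gray_level_cap,
    )
    t0 = time.time()
    features = extract_table(cases, registry, fcfg)
    timings["extract"] = time.time() - t0

    manifest = (
        manifest.set_index("case_id").loc[features.index]
        .rename_axis("case_id").reset_index()
    )
    labels = manifest["label"].to_numpy()
    split = manifest["split"].to_numpy()
    is_train = split == "train"
    is_test = split == "test"

    t0 = time.time()
    scaled, scaler = fit_apply_scaler(features, features.index[is_train])
    selected, selection = select_features(
        scaled.loc[features.index[is_train]], labels[is_train],
        method=cfg.selection.method, alpha=cfg.selection.alpha,
        top_n=cfg.selection.top_n, n_keep=cfg.selection.n_keep, seed=cfg.seed,
    )
    timings["select"] = time.time() - t0

    t0 = time.time()
    specs = [ClassifierSpec(kind=k, seed=cfg.seed) for k in cfg.model.kinds]
    rsv = build_rsv(
        scaled.loc[features.index[is_train], selected], labels[is_train],
        candidate_specs=specs, weight_grid=cfg.model.weight_grid,
        folds=cfg.model.folds, seed=cfg.seed,
    )
    timings["train"] = time.time() - t0

    t0 = time.time()
    test_ids = features.index[is_test]
    probs_truth = rsv.predict_proba(scaled.loc[test_ids, selected])
    metrics_rsv_truth = evaluate(probs_truth, labels[is_test])
    timings["evaluate_truth"] = time.time() - t0

    metrics_rsv_auto = metrics_edpk = None
    edpk_records: list[PredictionRecord] = []
    auto_probs = None
    if cfg.edpk.enabled:
        t0 = time.time()
        edpk_cfg = EDPKConfig(
            set_number=cfg.edpk.set_number, min_voxels=cfg.edpk.min_voxels,
            weight_high=cfg.edpk.weight_high,
            high_regime_fusion=cfg.edpk.high_regime_fusion,
        )
        seed_rng = np.random.default_rng(cfg.seed + 10_000)
        case_by_id = {c.case_id: c for c in cases}
        rows = []
        for case_id in test_ids:
            case = case_by_id[case_id]
            s1, s2 = (int(s) for s in seed_rng.integers(0, 2**31 - 1, 2))
            mask_g = corrupt_mask(case.truth_mask, cfg.edpk.target_dice, seed=s1)
            mask_m = corrupt_mask(
                mets_style_mask(case.truth_mask), cfg.edpk.target_dice, seed=s2
            )
            rec = edpk_predict(
                case.t1ce, case.t2flair, mask_g, mask_m, rsv, scaler, selected,
                config=edpk_cfg, registry=registry, filter_config=fcfg,
                case_id=case_id,
            )
            edpk_records.append(rec)
            fixed_prob = _fixed_rsv_predict_auto(
                case, mask_g, mask_m, rsv, scaler, selected, registry, fcfg,
                cfg.edpk.min_voxels, reuse_record=rec,
            )
            rows.append(
                {"case_id": case_id, "label": case.label,
                 "edpk_prob": rec.probability, "fixed_prob": fixed_prob}
            )
        auto_probs = pd.DataFrame(rows)
        metrics_edpk = evaluate(auto_probs["edpk_prob"], auto_probs["label"])
        metrics_rsv_auto = evaluate(auto_probs["fixed_prob"], auto_probs["label"])
        timings["edpk"] = time.time() - t0

    importance = None
    if cfg.explain.enabled:
        t0 = time.time()
        background = scaled.loc[features.index[is_train], selected]
        explanations = explain_cohort(
            lambda x: rsv.predict_proba(pd.DataFrame(x, columns=selected)),
            scaled.loc[test_ids, selected], background,
            n_permutations=cfg.explain.n_permutations, seed=cfg.seed,
            max_background=cfg.explain.max_background,
        )
        importance = importance_rank(explanations)
        timings["explain"] = time.time() - t0

    return RunResult(
        config=cfg, manifest=manifest, features=features,
        selected_features=selected, selection=selection, scaler=scaler,
        rsv=rsv, metrics_rsv_truth=metrics_rsv_truth,
        metrics_rsv_auto=metrics_rsv_auto, metrics_edpk=metrics_edpk,
        edpk_records=edpk_records, auto_probs=auto_probs,
        importance=importance, timings=timings,
    )


def write_artifacts(result: RunResult, outdir) -> Path:
    """Write the self-describing artifact directory for a run."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config_snapshot.yaml")
    result.manifest.to_csv(out / "manifest.csv", index=False)
    result.features.rename_axis("case_id").to_csv(out / "features.csv")

    with open(out / "selection.json", "w") as fh:
        fh.write(json.dumps(
            {name: json.loads(res.to_json()) for name, res in result.selection.items()},
            indent=2,
        ))
    pearson_matrix(result.features[result.selected_features]).to_csv(
        out / "correlation.csv"
    )

    metrics = {
        "selected_features": result.selected_features,
        "rsv_base_kinds": list(result.rsv.base_kinds),
        "rsv_weights": list(result.rsv.weights),
        "rsv_truth_roi": result.metrics_rsv_truth.to_dict(),
    }
    if result.metrics_rsv_auto is not None:
        metrics["rsv_fixed_auto_roi"] = result.metrics_rsv_auto.to_dict()
    if result.metrics_edpk is not None:
        metrics["rsv_edpk_auto_roi"] = result.metrics_edpk.to_dict()
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    # kept apart so metrics.json is bit-reproducible across identical runs
    with open(out / "timings.json", "w") as fh:
        json.dump({k: round(v, 3) for k, v in result.timings.items()}, fh, indent=2)

    result.metrics_rsv_truth.roc_points.to_csv(out / "roc_truth.csv", index=False)
    result.metrics_rsv_truth.calibration_bins.to_csv(
        out / "calibration_truth.csv", index=False
    )
    if result.edpk_records:
        with open(out / "edpk_decisions.json", "w") as fh:
            json.dump([r.to_dict() for r in result.edpk_records], fh, indent=2)
    if result.auto_probs is not None:
        result.auto_probs.to_csv(out / "auto_probs.csv", index=False)
    if result.importance is not None:
        result.importance.ranking.to_csv(out / "shap_ranking.csv", index=False)
        result.importance.phi_matrix.to_csv(out / "shap_values.csv", index=False)
    return out
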