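"""Ensemble decision strategy based on prior knowledge (EDPK).

Two automatic segmentations are produced per case (one by a glioma-trained
model, one by a mets-trained model).  After removing small false-positive
components, the lesion numbers L_G and L_M are counted and
``Number = max(L_G, L_M)`` drives the decision:

* ``Number < set_number`` (default 3) — the lesion pattern looks
  glioma-like: the two masks are merged into a single ROI and the vote
  weights are equal;
* otherwise — multiple lesions suggest metastases: both masks are kept,
  each is classified separately, and the vote weights switch to the
  high-multiplicity pair (default 2:1 on the better base model).

The strategy adapts both the ROI and the ensemble weights to the automatic
segmentation, buffering the classifier against segmentation uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ensemble import RSVModel, soft_vote
from .featsel import ScalerState
from .radiomics import FeatureRegistry, FilterConfig, extract_case
from .roi import count_lesions, merge_masks, remove_small_lesions, whole_roi
from .volume import SegMask, Volume, require_same_grid

HIGH_REGIME_FUSIONS = ("mean_of_masks", "glioma_mask_only", "mets_mask_only")


@dataclass
class EDPKConfig:
    set_number: int = 3
    min_voxels: int = 50
    connectivity: int = 26
    weight_low: tuple[float, float] = (1.0, 1.0)
    weight_high: tuple[float, float] = (2.0, 1.0)
    high_regime_fusion: str = "mean_of_masks"

    def __post_init__(self) -> None:
        if self.set_number < 1:
            raise ValueError("set_number must be >= 1")
        if any(w < 0 for w in self.weight_low + self.weight_high):
            raise ValueError("weights must be nonnegative")
        if self.weight_low[0] != self.weight_low[1]:
            raise ValueError("low-regime weights must be equal")
        if self.high_regime_fusion not in HIGH_REGIME_FUSIONS:
            raise ValueError(f"unknown fusion {self.high_regime_fusion!r}")


@dataclass
class EDPKDecision:
    """Auditable record of one decision: masks, counts, branch, weights."""

    mask_g: SegMask
    mask_m: SegMask
    l_g: int
    l_m: int
    number: int
    regime: str  # "low" | "high"
    final_mask_set: list[SegMask]
    weights: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "L_G": self.l_g,
            "L_M": self.l_m,
            "number": self.number,
            "regime": self.regime,
            "n_final_masks": len(self.final_mask_set),
            "weights": list(self.weights),
        }


def edpk_decide(
    predict_mask_g: SegMask,
    predict_mask_m: SegMask,
    config: EDPKConfig | None = None,
) -> EDPKDecision:
    """Post-process both masks, count lesions, and pick branch + weights."""
    config = config or EDPKConfig()
    require_same_grid(predict_mask_g, predict_mask_m)

    mask_g = remove_small_lesions(predict_mask_g, config.min_voxels, config.connectivity)
    mask_m = remove_small_lesions(predict_mask_m, config.min_voxels, config.connectivity)
    l_g = count_lesions(whole_roi(mask_g), config.connectivity).lesion_count
    l_m = count_lesions(whole_roi(mask_m), config.connectivity).lesion_count
    number = max(l_g, l_m)

    if number == 0:
        warnings.warn("both post-processed masks are empty; degenerate low-regime decision")
    if number < config.set_number:
        return EDPKDecision(
            mask_g=mask_g, mask_m=mask_m, l_g=l_g, l_m=l_m, number=number,
            regime="low", final_mask_set=[merge_masks(mask_g, mask_m)],
            weights=tuple(config.weight_low),
        )
    if config.high_regime_fusion == "glioma_mask_only":
        final = [mask_g]
    elif config.high_regime_fusion == "mets_mask_only":
        final = [mask_m]
    else:
        final = [mask_g, mask_m]
    return EDPKDecision(
        mask_g=mask_g, mask_m=mask_m, l_g=l_g, l_m=l_m, number=number,
        regime="high", final_mask_set=final, weights=tuple(config.weight_high),
    )


@dataclass
class PredictionRecord:
    case_id: str
    probability: float  # P(class 1 = mets)
    predicted_label: int
    per_mask_probability: list[float]
    decision: EDPKDecision
    features: list = field(default_factory=list)  # raw per-mask feature vectors

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "probability": self.probability,
            "predicted_label": self.predicted_label,
            "per_mask_probability": self.per_mask_probability,
            **self.decision.to_dict(),
        }


def edpk_predict(
    t1ce: Volume,
    t2flair: Volume,
    predict_mask_g: SegMask,
    predict_mask_m: SegMask,
    rsv: RSVModel,
    scaler: ScalerState,
    selected_features: list[str],
    config: EDPKConfig | None = None,
    registry: FeatureRegistry | None = None,
    filter_config: FilterConfig | None = None,
    case_id: str = "case",
    threshold: float = 0.5,
) -> PredictionRecord:
    """Classify one case under the EDPK strategy.

    For every mask in the final set: whole ROI -> feature extraction (with
    the decided lesion number) -> train-split scaling -> feature selection
    -> base-model probabilities -> soft vote with the decided weights.  In
    the high regime with two masks, the two vote outputs are averaged.
    """
    config = config or EDPKConfig()
    decision = edpk_decide(predict_mask_g, predict_mask_m, config)

    import pandas as pd

    per_mask: list[float] = []
    vectors = []
    for mask in decision.final_mask_set:
        roi = whole_roi(mask)
        if not roi.any():
            raise ValueError(f"case {case_id}: final ROI is empty")
        vec = extract_case(
            t1ce, t2flair, roi, decision.number,
            registry=registry, config=filter_config,
        )
        vectors.append(vec)
        row = pd.DataFrame([vec])
        scaled = scaler.transform(row)[selected_features]
        probs = [m.predict_proba(scaled.to_numpy())[:, 1] for m in rsv.base_models]
        per_mask.append(float(soft_vote(probs, decision.weights)[0]))

    prob = float(np.mean(per_mask))
    return PredictionRecord(
        case_id=case_id,
        probability=prob,
        predicted_label=int(prob >= threshold),
        per_mask_probability=per_mask,
        decision=decision,
        features=vectors,
    )
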