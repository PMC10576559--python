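"""Canonical pipeline configurations for the package's validation studies.

These fix the synthetic study conditions (cohort sizes, lesion geometry,
segmentation degradation) used by the test suite and the reproduction
script, so both exercise identical scenarios.
"""

from __future__ import annotations

from .config import PipelineConfig


def recovery_cohort_config(seed: int = 0) -> PipelineConfig:
    """n=200 two-class cohort with informative shape + multiplicity signal.

    Used for parameter-recovery validation of the radiologist-ROI pipeline
    (no mask degradation): the planted class differences are lesion
    multiplicity and lesion size/shape.
    """
    return PipelineConfig.from_dict({
        "seed": seed,
        "output_dir": "runs/recovery",
        "phantom": {
            "n_glioma": 100, "n_mets": 100,
            "grid_shape": [64, 64, 48],
            "glioma_radius_mm": [6.0, 11.0],
            "mets_radius_mm": [3.5, 6.5],
            "mets_lesion_counts": [1, 2, 3, 4, 5, 6],
            "split_fractions": [0.6, 0.2, 0.2],
        },
        "model": {
            "folds": 10,
            "kinds": ["gnb", "logreg_l1", "svm_rbf", "random_forest"],
        },
        "selection": {"method": "lasso"},
        "edpk": {"enabled": False},
        "explain": {"enabled": False},
    })


def edpk_comparison_config(seed: int = 0) -> PipelineConfig:
    """n=60 cohort with automatic masks degraded to Dice ~0.85.

    Used for the EDPK-vs-fixed-weight comparison under imperfect
    segmentation.
    """
    return PipelineConfig.from_dict({
        "seed": seed,
        "output_dir": "runs/edpk",
        "phantom": {
            "n_glioma": 30, "n_mets": 30,
            "grid_shape": [64, 64, 48],
            "glioma_radius_mm": [6.0, 11.0],
            "mets_radius_mm": [3.5, 6.5],
            "mets_lesion_counts": [1, 2, 3, 4, 5, 6],
            "split_fractions": [0.6, 0.2, 0.2],
        },
        "model": {
            "folds": 5,
            "kinds": ["logreg_l1", "svm_rbf", "random_forest"],
        },
        "selection": {"method": "lasso"},
        "edpk": {"enabled": True, "target_dice": 0.85},
        "explain": {"enabled": False},
    })


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small cohort exercising every stage (EDPK and explanations included)."""
    return PipelineConfig.from_dict({
        "seed": seed,
        "output_dir": "runs/demo",
        "phantom": {
            "n_glioma": 12, "n_mets": 12,
            "grid_shape": [48, 48, 40],
            "glioma_radius_mm": [5.0, 8.0],
            "mets_radius_mm": [3.0, 5.0],
            "mets_lesion_counts": [1, 2, 3, 4],
            "split_fractions": [0.5, 0.25, 0.25],
        },
        "model": {"folds": 3, "kinds": ["gnb", "logreg_l1", "random_forest"]},
        "selection": {"method": "lasso"},
        "edpk": {"enabled": True, "target_dice": 0.85},
        "explain": {"enabled": True, "n_permutations": 50},
    })
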