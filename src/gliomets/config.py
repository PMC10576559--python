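"""Structured pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


def _build(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in config section '{section}': {sorted(unknown)}")
    return cls(**data)


def _tup(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x


@dataclass
class PhantomConfig:
    n_glioma: int = 20
    n_mets: int = 20
    grid_shape: tuple = (64, 64, 48)
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    split_fractions: tuple = (0.6, 0.2, 0.2)
    noise_sd: float = 5.0
    glioma_radius_mm: tuple = (6.0, 11.0)
    mets_radius_mm: tuple = (3.0, 6.0)
    glioma_lesion_counts: tuple = (1, 1, 1, 1, 2)
    mets_lesion_counts: tuple = (1, 2, 3, 4, 5, 6, 7, 8)

    def __post_init__(self):
        for name in ("grid_shape", "spacing_mm", "split_fractions", "glioma_radius_mm",
                     "mets_radius_mm", "glioma_lesion_counts", "mets_lesion_counts"):
            setattr(self, name, _tup(getattr(self, name)))


@dataclass
class PreprocessConfig:
    target_spacing_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.target_spacing_mm = _tup(self.target_spacing_mm)


@dataclass
class RoiConfig:
    min_voxels: int = 50
    connectivity: int = 26


@dataclass
class FeaturesConfig:
    log_sigmas_mm: tuple = (3.0, 5.0)
    wavelet_family: str = "coif1"
    bin_width: float = 0.25  # Z-scored intensities
    gray_level_cap: int | None = None

    def __post_init__(self):
        self.log_sigmas_mm = _tup(self.log_sigmas_mm)


@dataclass
class SelectionConfig:
    alpha: float = 0.05
    method: str = "lasso"  # lasso | mi | rfe_rf | lasso+mi | lasso+rfe_rf
    top_n: int = 20
    n_keep: int = 20


@dataclass
class ModelConfig:
    folds: int = 10
    kinds: tuple = ("gnb", "logreg_l1", "svm_poly", "svm_rbf", "random_forest",
                    "gradient_boosted_trees")
    weight_grid: tuple = ((1, 1), (2, 1), (2, 3), (4, 3), (3, 1))

    def __post_init__(self):
        self.kinds = _tup(self.kinds)
        self.weight_grid = tuple(tuple(w) for w in self.weight_grid)


@dataclass
class EdpkConfig:
    enabled: bool = True
    set_number: int = 3
    min_voxels: int = 50
    weight_high: tuple = (2.0, 1.0)
    target_dice: float = 0.85
    high_regime_fusion: str = "mean_of_masks"

    def __post_init__(self):
        self.weight_high = _tup(self.weight_high)


@dataclass
class ExplainConfig:
    enabled: bool = True
    n_permutations: int = 100
    top_k: int = 20
    max_background: int = 100


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "runs/out"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    edpk: EdpkConfig = field(default_factory=EdpkConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sections = {
            "phantom": PhantomConfig, "preprocess": PreprocessConfig,
            "roi": RoiConfig, "features": FeaturesConfig,
            "selection": SelectionConfig, "model": ModelConfig,
            "edpk": EdpkConfig, "explain": ExplainConfig,
        }
        kwargs: dict = {}
        for key in ("seed", "output_dir"):
            if key in data:
                kwargs[key] = data.pop(key)
        for name, section_cls in sections.items():
            if name in data:
                kwargs[name] = _build(section_cls, data.pop(name) or {}, name)
        if data:
            raise ValueError(f"unknown top-level config key(s): {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
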