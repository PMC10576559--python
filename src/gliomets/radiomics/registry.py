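"""Feature registry: the fixed catalogue of radiomics features.

Per MRI sequence the pipeline extracts

* 14 shape features (mask only, original image type),
* 18 first-order features on each of 11 image types
  (original + 2 LoG scales + 8 wavelet subbands) = 198,
* 68 texture features (GLCM 22, GLDM 14, GLRLM 16, GLSZM 16) on each of the
  11 image types = 748,

for a total of 960 per sequence; the two sequences plus the lesion-number
clinical feature give a 1921-long case vector.  The GLCM list omits two
conventionally redundant members (SumAverage, which duplicates JointAverage
for a symmetric matrix, and the maximal correlation coefficient); the
first-order list omits StandardDeviation (redundant with Variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

SHAPE_FEATURES: tuple[str, ...] = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)

FIRST_ORDER_FEATURES: tuple[str, ...] = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

#: excluded from the 24-feature conventional GLCM list, see module docstring
GLCM_EXCLUDED: tuple[str, ...] = ("SumAverage", "MaximalCorrelationCoefficient")

GLCM_FEATURES: tuple[str, ...] = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)

GLDM_FEATURES: tuple[str, ...] = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

GLRLM_FEATURES: tuple[str, ...] = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES: tuple[str, ...] = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

TEXTURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "glcm": GLCM_FEATURES,
    "gldm": GLDM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
}

WAVELET_SUBBANDS: tuple[str, ...] = (
    "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH",
)

LESION_NUMBER_COLUMN = "lesion_number"


def log_image_type(sigma_mm: float) -> str:
    return "log-sigma-" + f"{float(sigma_mm):.1f}".replace(".", "-") + "-mm"


@dataclass(frozen=True)
class FeatureRegistry:
    """Named feature catalogue with its count invariants checked up front."""

    log_sigmas_mm: tuple[float, ...] = (3.0, 5.0)
    shape: tuple[str, ...] = SHAPE_FEATURES
    first_order: tuple[str, ...] = FIRST_ORDER_FEATURES
    glcm: tuple[str, ...] = GLCM_FEATURES
    gldm: tuple[str, ...] = GLDM_FEATURES
    glrlm: tuple[str, ...] = GLRLM_FEATURES
    glszm: tuple[str, ...] = GLSZM_FEATURES
    wavelet_subbands: tuple[str, ...] = WAVELET_SUBBANDS
    sequences: tuple[str, ...] = ("t1ce", "flair")

    def __post_init__(self) -> None:
        if len(self.shape) != 14:
            raise ValueError(f"shape family must have 14 features, got {len(self.shape)}")
        if len(self.first_order) != 18:
            raise ValueError(
                f"first-order family must have 18 features, got {len(self.first_order)}"
            )
        n_tex = len(self.glcm) + len(self.gldm) + len(self.glrlm) + len(self.glszm)
        if n_tex != 68:
            raise ValueError(f"texture families must total 68 features, got {n_tex}")

    @property
    def image_types(self) -> tuple[str, ...]:
        return (
            ("original",)
            + tuple(log_image_type(s) for s in self.log_sigmas_mm)
            + tuple(f"wavelet-{b}" for b in self.wavelet_subbands)
        )

    @property
    def texture_families(self) -> dict[str, tuple[str, ...]]:
        return {
            "glcm": self.glcm,
            "gldm": self.gldm,
            "glrlm": self.glrlm,
            "glszm": self.glszm,
        }

    def sequence_feature_names(self, sequence: str) -> list[str]:
        """Registry-ordered column names for one sequence (length 960)."""
        names = [f"{sequence}_original_shape_{f}" for f in self.shape]
        for itype in self.image_types:
            names += [f"{sequence}_{itype}_firstorder_{f}" for f in self.first_order]
            for fam, feats in self.texture_families.items():
                names += [f"{sequence}_{itype}_{fam}_{f}" for f in feats]
        return names

    def case_feature_names(self) -> list[str]:
        """All 2 x 960 + 1 column names in stable registry order."""
        names: list[str] = []
        for seq in self.sequences:
            names += self.sequence_feature_names(seq)
        names.append(LESION_NUMBER_COLUMN)
        return names

    @property
    def features_per_sequence(self) -> int:
        return len(self.sequence_feature_names(self.sequences[0]))
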