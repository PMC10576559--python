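"""First-order (intensity histogram) features of the ROI.

All moments are population moments.  Entropy and Uniformity are computed
on the fixed-bin-width discretized histogram; everything else on the raw
intensities.  Conventions for a constant ROI: Variance 0, Uniformity 1,
Entropy 0, Skewness 0, Kurtosis 0.
"""

from __future__ import annotations

import numpy as np

from .registry import FIRST_ORDER_FEATURES


def first_order_features(
    values: np.ndarray,
    bins: np.ndarray,
    voxel_volume_mm3: float,
) -> dict[str, float]:
    """The 18 first-order descriptors.

    Parameters
    ----------
    values
        Raw intensities of the ROI voxels (1D).
    bins
        Discretized gray levels of the same voxels (1D, values >= 1).
    voxel_volume_mm3
        Physical voxel volume, used by TotalEnergy.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError(f"first-order features need >= 2 ROI voxels, got {x.size}")
    b = np.asarray(bins).ravel()
    if b.size != x.size:
        raise ValueError("values and bins must align")

    p = np.bincount(b)[1:].astype(np.float64)
    p = p[p > 0] / x.size

    mean = float(x.mean())
    var = float(x.var())  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    m2 = var
    if m2 > 0:
        m3 = float(np.mean((x - mean) ** 3))
        m4 = float(np.mean((x - mean) ** 4))
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2
    else:
        skewness = 0.0
        kurtosis = 0.0

    values_out = {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume_mm3 * np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skewness),
        "Kurtosis": float(kurtosis),
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }
    assert tuple(values_out) == FIRST_ORDER_FEATURES
    return values_out
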