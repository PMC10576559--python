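"""Per-case feature extraction: filter bank x feature families.

For each of the two sequences: shape (14, mask only, reported under the
``original`` image type) + first-order (18) and texture (68) on each of the
11 image types (original, 2 LoG scales, 8 wavelet subbands) = 960 values;
the lesion-number clinical feature completes the 1921-long case vector.

Extraction crops to the ROI bounding box (plus a context margin that covers
the filter supports) before filtering, which changes nothing inside the ROI
but keeps single-case extraction fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..volume import Volume, require_same_grid
from .filters import FilterConfig, discretize, log_filter, wavelet_decompose
from .firstorder import first_order_features
from .registry import LESION_NUMBER_COLUMN, FeatureRegistry, log_image_type
from .shape import shape_features
from .texture import texture_features


class FeatureExtractionError(RuntimeError):
    pass


def _crop_slices(roi: np.ndarray, margin_vox: int) -> tuple[slice, slice, slice]:
    idx = np.argwhere(roi)
    lo = np.maximum(idx.min(axis=0) - margin_vox, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin_vox, roi.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _image_bank(vol: Volume, registry: FeatureRegistry, config: FilterConfig):
    """The 11 image types of one sequence, in registry order."""
    bank = {"original": vol}
    for sigma in config.log_sigmas_mm:
        bank[log_image_type(sigma)] = log_filter(vol, sigma)
    for name, sub in wavelet_decompose(
        vol, config.wavelet_family, config.wavelet_mode
    ).items():
        bank[f"wavelet-{name}"] = sub
    return bank


def extract_sequence(
    vol: Volume,
    roi: np.ndarray,
    sequence: str,
    registry: FeatureRegistry,
    config: FilterConfig,
    shape_values: dict[str, float] | None = None,
) -> dict[str, float]:
    """All 960 features of one sequence, keyed by full column name."""
    roi = np.asarray(roi).astype(bool)
    if roi.shape != vol.shape:
        raise ValueError("ROI must share the volume grid")
    if int(roi.sum()) < 2:
        raise FeatureExtractionError(
            f"{sequence}: ROI must contain >= 2 voxels, got {int(roi.sum())}"
        )

    # loose crop covering filter supports, then tight crop for the families
    wav_half = 8  # longest supported wavelet filters are well under 17 taps
    margin = max(
        int(np.ceil(3.0 * max(config.log_sigmas_mm) / min(vol.spacing))), wav_half
    )
    loose = _crop_slices(roi, margin)
    sub_vol = Volume(
        data=np.asarray(vol.data, dtype=np.float64)[loose], spacing=vol.spacing
    )
    sub_roi = roi[loose]
    tight = _crop_slices(sub_roi, 1)
    roi_t = sub_roi[tight]
    voxel_volume = float(np.prod(vol.spacing))

    out: dict[str, float] = {}
    shape_vals = shape_values or shape_features(roi_t, vol.spacing)
    for name, value in shape_vals.items():
        out[f"{sequence}_original_shape_{name}"] = value

    for itype, image in _image_bank(sub_vol, registry, config).items():
        data_t = np.asarray(image.data)[tight]
        try:
            bins_grid, n_levels = discretize(
                data_t, roi_t, config.bin_width, config.gray_level_cap
            )
            fo = first_order_features(
                data_t[roi_t], bins_grid[roi_t], voxel_volume
            )
            tex = texture_features(bins_grid, n_levels)
        except ValueError as exc:
            raise FeatureExtractionError(f"{sequence}/{itype}: {exc}") from exc
        for name, value in fo.items():
            out[f"{sequence}_{itype}_firstorder_{name}"] = value
        for family, feats in tex.items():
            for name, value in feats.items():
                out[f"{sequence}_{itype}_{family}_{name}"] = value
    return out


def extract_case(
    t1ce: Volume,
    t2flair: Volume,
    roi: np.ndarray,
    lesion_count: int,
    registry: FeatureRegistry | None = None,
    config: FilterConfig | None = None,
) -> pd.Series:
    """The full 1921-value case vector in stable registry column order."""
    registry = registry or FeatureRegistry()
    config = config or FilterConfig(log_sigmas_mm=registry.log_sigmas_mm)
    require_same_grid(t1ce, t2flair)

    roi = np.asarray(roi).astype(bool)
    tight = _crop_slices(roi, 1) if roi.any() else None
    if tight is None:
        raise FeatureExtractionError("ROI is empty")
    shape_vals = shape_features(roi[tight], t1ce.spacing)

    values: dict[str, float] = {}
    for seq, vol in (("t1ce", t1ce), ("flair", t2flair)):
        values.update(
            extract_sequence(vol, roi, seq, registry, config, shape_values=shape_vals)
        )
    values[LESION_NUMBER_COLUMN] = float(lesion_count)

    columns = registry.case_feature_names()
    missing = set(columns) - set(values)
    if missing:
        raise FeatureExtractionError(f"missing features: {sorted(missing)[:5]}...")
    return pd.Series([values[c] for c in columns], index=columns, dtype=float)
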