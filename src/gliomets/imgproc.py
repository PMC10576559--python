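"""Image standardization: isotropic resampling and Z-score intensity
normalization over the brain area.

All MRI volumes are resampled to a common (by default 1x1x1 mm) grid so that
voxel counts and physical sizes are comparable across scanners, then each
sequence is rescaled to zero mean / unit standard deviation over the brain
mask.  The package assumes the two sequences of a case are already
co-registered (identical grids) and raises otherwise; bias-field correction
and registration are out of scope.

Z-scoring uses the population standard deviation (ddof=0).
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk

from .volume import SegMask, Volume


def _to_sitk(data: np.ndarray, spacing: tuple[float, float, float]) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); our convention is (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))


def _resampled_affine(affine: np.ndarray, in_spacing, target) -> np.ndarray:
    out = np.asarray(affine, dtype=float).copy()
    for i in range(3):
        direction = out[:3, i] / float(in_spacing[i])
        out[:3, i] = direction * float(target[i])
        # cell-centered alignment: voxel-0 center shifts by half the change
        out[:3, 3] += direction * 0.5 * (float(target[i]) - float(in_spacing[i]))
    return out


def resample_isotropic(
    vol: Volume,
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    interpolation: str = "linear",
) -> Volume:
    """Resample a volume to the requested voxel spacing.

    Output dimension per axis is ``round(in_dim * in_spacing / target)``, so
    the physical extent is preserved to within one voxel.  ``nearest``
    interpolation must be used for label masks.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if np.allclose(vol.spacing, target):
        return vol.copy()

    in_dim = vol.shape
    out_dim = tuple(
        max(1, int(round(in_dim[i] * vol.spacing[i] / target[i]))) for i in range(3)
    )
    img = _to_sitk(np.asarray(vol.data, dtype=np.float64), vol.spacing)
    rf = sitk.ResampleImageFilter()
    rf.SetOutputSpacing(target)
    rf.SetSize(tuple(int(d) for d in out_dim))
    # cell-centered grids: voxel-0 center moves by half the spacing change
    origin = tuple(
        o + 0.5 * (t - s) for o, t, s in zip(img.GetOrigin(), target, vol.spacing)
    )
    rf.SetOutputOrigin(origin)
    rf.SetOutputDirection(img.GetDirection())
    rf.SetUseNearestNeighborExtrapolator(True)
    rf.SetInterpolator(
        sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    )
    out = _from_sitk(rf.Execute(img))
    return Volume(
        data=out,
        spacing=target,
        affine=_resampled_affine(vol.affine, vol.spacing, target),
    )


def resample_mask(mask: SegMask, target_spacing_mm=(1.0, 1.0, 1.0)) -> SegMask:
    """Nearest-neighbour resampling of a label mask (label set preserved)."""
    vol = Volume(
        data=np.asarray(mask.labels, dtype=np.float64),
        spacing=mask.spacing,
        affine=mask.affine,
    )
    res = resample_isotropic(vol, target_spacing_mm, interpolation="nearest")
    return SegMask(
        labels=np.rint(res.data).astype(np.int16),
        spacing=res.spacing,
        affine=res.affine,
    )


def znorm_image(vol: Volume, brain_mask: np.ndarray) -> Volume:
    """Z-score normalize intensities over the brain mask.

    Voxels outside the mask are set to 0.  Raises on an empty mask or a
    constant brain region (zero variance), which leaves the transform
    undefined.
    """
    brain = np.asarray(brain_mask).astype(bool)
    if brain.shape != vol.shape:
        raise ValueError("brain mask must share the volume grid")
    if not brain.any():
        raise ValueError("brain mask is empty")
    vals = vol.data[brain]
    mu = float(vals.mean())
    sd = float(vals.std())  # population sd
    if sd == 0.0:
        raise ValueError("degenerate input: zero intensity variance over the brain mask")
    out = np.zeros_like(vol.data, dtype=np.float64)
    out[brain] = (vals - mu) / sd
    return vol.with_data(out)


def brain_mask_of(vol: Volume) -> np.ndarray:
    """Brain area at phantom scale: all nonzero voxels (phantoms carry no skull)."""
    return np.asarray(vol.data) != 0
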