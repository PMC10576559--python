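"""Filter bank and gray-level discretization.

Two band-pass views complement the original image: the Laplacian of
Gaussian at physical scales sigma (mm), highlighting blob-like structure of
matching size, and a one-level separable 3D wavelet decomposition into
eight subbands (all low/high-pass combinations per axis).  The wavelet bank
is applied undecimated with zero padding, so every subband lives on the
original voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from ..volume import Volume
from .registry import WAVELET_SUBBANDS


@dataclass
class FilterConfig:
    """Knobs of the filter bank and discretization.

    ``bin_width`` is in image intensity units; the default 25 follows the
    raw-intensity radiomics convention — pipelines running on Z-scored
    images should set a width of the order of 0.25 so that a few tens of
    gray levels result.
    """

    log_sigmas_mm: tuple[float, ...] = (3.0, 5.0)
    wavelet_family: str = "coif1"
    wavelet_mode: str = "constant"  # zero padding
    bin_width: float = 25.0
    gray_level_cap: int | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError(f"LoG sigmas must be positive, got {self.log_sigmas_mm}")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")


def log_filter(vol: Volume, sigma_mm: float) -> Volume:
    """Laplacian-of-Gaussian response at physical scale ``sigma_mm``.

    The Gaussian is spacing-aware (sigma converted to voxels per axis) and
    the Laplacian sums physical second derivatives, so the response is
    comparable across anisotropic grids.
    """
    if sigma_mm <= 0:
        raise ValueError(f"sigma must be positive, got {sigma_mm}")
    data = np.asarray(vol.data, dtype=np.float64)
    sig_vox = [sigma_mm / s for s in vol.spacing]
    out = np.zeros_like(data)
    for axis in range(3):
        order = [0, 0, 0]
        order[axis] = 2
        # wide truncation keeps the derivative kernel's numerical sum at zero
        out += (
            ndimage.gaussian_filter(
                data, sigma=sig_vox, order=order, mode="nearest", truncate=8.0
            )
            / vol.spacing[axis] ** 2
        )
    return vol.with_data(out)


def wavelet_decompose(
    vol: Volume, family: str = "coif1", mode: str = "constant"
) -> dict[str, Volume]:
    """One-level undecimated 3D wavelet decomposition into 8 subbands.

    Subband names are three letters (L = low-pass, H = high-pass) in axis
    order (x, y, z); every subband shares the input grid.
    """
    wav = pywt.Wavelet(family)
    lo = np.asarray(wav.dec_lo, dtype=np.float64)
    hi = np.asarray(wav.dec_hi, dtype=np.float64)
    if min(vol.shape) < len(lo):
        raise ValueError(
            f"axis too short for {family} filters (length {len(lo)}): shape {vol.shape}"
        )
    data = np.asarray(vol.data, dtype=np.float64)
    out: dict[str, Volume] = {}
    for name in WAVELET_SUBBANDS:
        sub = data
        for axis, letter in enumerate(name):
            weights = lo if letter == "L" else hi
            sub = ndimage.convolve1d(sub, weights, axis=axis, mode=mode, cval=0.0)
        out[name] = vol.with_data(sub)
    return out


def discretize(
    data: np.ndarray,
    roi: np.ndarray,
    bin_width: float,
    gray_level_cap: int | None = None,
) -> tuple[np.ndarray, int]:
    """Fixed-bin-width gray-level discretization within the ROI.

    Returns an integer grid (0 outside the ROI, bins 1..Ng inside) and the
    bin count Ng.  Bin index = floor((x - min_roi) / bin_width) + 1.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    roi = np.asarray(roi).astype(bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    vals = np.asarray(data, dtype=np.float64)[roi]
    bins = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    if gray_level_cap is not None:
        bins = np.minimum(bins, int(gray_level_cap))
    out = np.zeros(np.asarray(data).shape, dtype=np.int64)
    out[roi] = bins
    return out, int(bins.max())
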