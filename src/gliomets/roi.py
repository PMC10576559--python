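"""Mask algebra for tumor regions of interest.

The whole ROI is the union of the compartments (edema + enhancing +
necrotic); lesions are counted as 3D connected components of that union.
These operations underpin both feature extraction and the lesion-count
branch of the ensemble decision strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import LABEL_PRECEDENCE, SegMask, require_same_grid

#: default voxel-count threshold below which a connected component is treated
#: as a false-positive lesion (~50 mm^3 at 1 mm isotropic spacing)
DEFAULT_MIN_VOXELS = 50

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTURES[int(connectivity)]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}") from None


@dataclass
class LesionSummary:
    """Connected-component census of a binary lesion mask."""

    component_sizes: list[int] = field(default_factory=list)
    connectivity: int = 26

    @property
    def lesion_count(self) -> int:
        return len(self.component_sizes)

    def to_dict(self) -> dict:
        return {
            "lesion_count": self.lesion_count,
            "component_sizes": [int(s) for s in self.component_sizes],
            "connectivity": self.connectivity,
        }


def whole_roi(mask: SegMask) -> np.ndarray:
    """Binary union of all compartments: 1 wherever the label is > 0."""
    return np.asarray(mask.labels) > 0


def count_lesions(binary: np.ndarray, connectivity: int = 26) -> LesionSummary:
    """Enumerate 3D connected components of a binary mask.

    Sizes are reported in voxels, sorted descending.
    """
    arr = np.asarray(binary)
    if not (arr.dtype == bool or set(np.unique(arr)).issubset({0, 1})):
        raise TypeError("count_lesions expects a binary mask")
    labeled, n = ndimage.label(arr.astype(bool), structure=_structure(connectivity))
    sizes = np.bincount(labeled.ravel())[1:] if n else np.array([], dtype=int)
    return LesionSummary(
        component_sizes=sorted((int(s) for s in sizes), reverse=True),
        connectivity=int(connectivity),
    )


def remove_small_lesions(
    mask: SegMask, min_voxels: int = DEFAULT_MIN_VOXELS, connectivity: int = 26
) -> SegMask:
    """Delete whole-ROI connected components smaller than ``min_voxels``.

    Surviving components keep their compartment labels untouched.
    """
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    if min_voxels == 0:
        return mask.copy()
    roi = whole_roi(mask)
    labeled, n = ndimage.label(roi, structure=_structure(connectivity))
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labeled.ravel())
    kill = np.zeros(n + 1, dtype=bool)
    kill[1:] = sizes[1:] < min_voxels
    out = np.asarray(mask.labels).copy()
    out[kill[labeled]] = 0
    return mask.with_labels(out)


def merge_masks(a: SegMask, b: SegMask) -> SegMask:
    """Voxelwise union of two compartment masks.

    At voxels claimed by both masks with different labels, the innermost
    compartment wins (necrotic > enhancing > edema), which makes the merge
    order-independent.
    """
    require_same_grid(a, b)
    la, lb = np.asarray(a.labels), np.asarray(b.labels)
    out = np.zeros_like(la)
    # paint outermost first so inner compartments overwrite at contested voxels
    for lab in reversed(LABEL_PRECEDENCE):
        out[(la == lab) | (lb == lab)] = lab
    return a.with_labels(out)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
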