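"""Spatial containers for MRI volumes and compartment masks.

Conventions used throughout the package:

* arrays are indexed ``(x, y, z)`` with 0-based voxel indices, axis order
  aligned to the NIfTI affine;
* ``spacing`` is the physical voxel size in mm per axis;
* mask label semantics: 0 background, 1 peritumoral edema, 2 enhancing
  tumor, 3 necrotic core.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

LABEL_BACKGROUND = 0
LABEL_EDEMA = 1
LABEL_ENHANCING = 2
LABEL_NECROTIC = 3

#: label painted on top when compartments overlap (innermost wins)
LABEL_PRECEDENCE = (LABEL_NECROTIC, LABEL_ENHANCING, LABEL_EDEMA)


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume:
    """A 3D scalar image with physical voxel spacing (mm) and affine."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data contains non-finite values")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy(), affine=self.affine.copy())

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same grid, new voxel values."""
        return replace(self, data=np.asarray(data), affine=self.affine.copy())


@dataclass
class SegMask:
    """Integer-labeled compartment mask sharing a :class:`Volume` grid."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"SegMask labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.all(lab == np.round(lab)):
                raise TypeError("SegMask labels must be integer-valued")
            self.labels = lab.astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_set(self) -> set[int]:
        return set(int(v) for v in np.unique(self.labels))

    def copy(self) -> "SegMask":
        return replace(self, labels=self.labels.copy(), affine=self.affine.copy())

    def with_labels(self, labels: np.ndarray) -> "SegMask":
        return replace(self, labels=np.asarray(labels), affine=self.affine.copy())


def same_grid(a: Volume | SegMask, b: Volume | SegMask) -> bool:
    return a.shape == b.shape and np.allclose(a.spacing, b.spacing)


def require_same_grid(a: Volume | SegMask, b: Volume | SegMask) -> None:
    if not same_grid(a, b):
        raise ValueError(
            f"grid mismatch: shape/spacing {a.shape}/{a.spacing} vs {b.shape}/{b.spacing}"
        )


# ---------------------------------------------------------------------------
# NIfTI round trip


def load_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def save_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_mask(path) -> SegMask:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SegMask(labels=np.rint(data).astype(np.int16), spacing=spacing,
                   affine=np.asarray(img.affine))


def save_mask(mask: SegMask, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask.labels, dtype=np.int16), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
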