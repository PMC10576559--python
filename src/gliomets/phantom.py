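"""Synthetic two-sequence brain-tumor phantoms.

The generator emulates the two tumor classes the classifier must separate:

* **glioma** — a single (occasionally double) large, irregular lesion with
  three compartments: enhancing rim, necrotic core, peritumoral edema;
* **brain metastases (mets)** — 1-8 smaller, rounder lesions with two
  compartments: enhancing tumor and peritumoral edema.

Each case carries a T1-CE-like and a T2-FLAIR-like channel in which the
compartments differ by mean intensity (enhancing bright on T1-CE, edema
bright on FLAIR, necrosis dark on T1-CE) plus additive Gaussian noise.  This
mimics the contrast semantics radiologists use, not quantitative MR physics.

``corrupt_mask`` stands in for an automatic segmentation network: it
degrades a ground-truth mask to a requested whole-ROI Dice coefficient by
adding smooth boundary noise, then injects small spurious components of the
kind post-processing is meant to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .roi import count_lesions, whole_roi
from .volume import (
    LABEL_EDEMA,
    LABEL_ENHANCING,
    LABEL_NECROTIC,
    SegMask,
    Volume,
)

SEQUENCES = ("t1ce", "flair")

#: default compartment mean intensities per sequence (arbitrary units)
DEFAULT_CONTRAST = {
    "t1ce": {"background": 80.0, "edema": 90.0, "enhancing": 160.0, "necrotic": 40.0},
    "flair": {"background": 80.0, "edema": 170.0, "enhancing": 120.0, "necrotic": 110.0},
}

GLIOMA, METS = "glioma", "mets"
LABEL_OF_TYPE = {GLIOMA: 0, METS: 1}


@dataclass
class PhantomSpec:
    """Full recipe for one synthetic case (deterministic given ``seed``)."""

    tumor_type: Literal["glioma", "mets"]
    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_count: int = 1
    lesion_radius_mm: tuple[float, float] = (8.0, 16.0)
    shape_irregularity: float = 0.4
    compartment_contrast: dict = field(default_factory=lambda: DEFAULT_CONTRAST)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_type not in (GLIOMA, METS):
            raise ValueError(f"tumor_type must be 'glioma' or 'mets', got {self.tumor_type!r}")
        lo, hi = (1, 2) if self.tumor_type == GLIOMA else (1, 8)
        if not (lo <= self.lesion_count <= hi):
            raise ValueError(
                f"lesion_count for {self.tumor_type} must lie in [{lo}, {hi}], "
                f"got {self.lesion_count}"
            )
        if not (0.0 <= self.shape_irregularity <= 1.0):
            raise ValueError("shape_irregularity must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.lesion_radius_mm[0] <= 0 or self.lesion_radius_mm[1] < self.lesion_radius_mm[0]:
            raise ValueError(f"invalid lesion_radius_mm range {self.lesion_radius_mm}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")


@dataclass
class CaseRecord:
    """One simulated patient: two co-registered channels plus ground truth."""

    case_id: str
    t1ce: Volume
    t2flair: Volume
    truth_mask: SegMask
    label: int  # 0 = glioma, 1 = mets
    lesion_count_truth: int


class LesionPlacementError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# geometry helpers


def _brain_support(shape, spacing) -> np.ndarray:
    """Ellipsoid filling ~90% of the grid, standing in for the brain."""
    coords = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)],
        indexing="ij",
    )
    semi = [0.45 * n * s for n, s in zip(shape, spacing)]
    q = sum((c / a) ** 2 for c, a in zip(coords, semi))
    return q <= 1.0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _paint_ellipsoid(field_arr, center_mm, semi_mm, rot, spacing) -> None:
    """Set voxels inside a rotated ellipsoid to 1 (bounding-box local)."""
    shape = field_arr.shape
    rmax = float(np.max(semi_mm))
    lo = [max(0, int((center_mm[i] - rmax) / spacing[i]) - 1) for i in range(3)]
    hi = [min(shape[i], int((center_mm[i] + rmax) / spacing[i]) + 2) for i in range(3)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    grids = np.meshgrid(
        *[np.arange(lo[i], hi[i]) * spacing[i] - center_mm[i] for i in range(3)],
        indexing="ij",
    )
    pts = np.stack([g.ravel() for g in grids])
    local = rot.T @ pts
    q = sum((local[i] / semi_mm[i]) ** 2 for i in range(3))
    inside = (q <= 1.0).reshape([h - l for l, h in zip(lo, hi)])
    sub = field_arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[inside] = 1.0


def _lesion_mask(rng, shape, spacing, center_mm, radius_mm, irregularity) -> np.ndarray:
    """Irregular lesion: union of perturbed ellipsoids, smoothed by 1 voxel."""
    indicator = np.zeros(shape, dtype=np.float32)
    semi = radius_mm * rng.uniform(1.0 - 0.3 * irregularity, 1.0 + 0.3 * irregularity, 3)
    _paint_ellipsoid(indicator, center_mm, semi, _random_rotation(rng), spacing)
    n_bumps = int(round(1 + 4 * irregularity))
    for _ in range(n_bumps):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        offset = center_mm + direction * radius_mm * rng.uniform(0.3, 0.7)
        bump_semi = radius_mm * rng.uniform(0.35, 0.6, 3)
        _paint_ellipsoid(indicator, offset, bump_semi, _random_rotation(rng), spacing)
    smoothed = ndimage.gaussian_filter(indicator, sigma=1.0)
    return smoothed > 0.5


def _place_centers(rng, spec: PhantomSpec, radii_mm, edema_mm) -> np.ndarray:
    """Sample lesion centers inside the brain, keeping whole lesions apart."""
    shape, spacing = spec.grid_shape, spec.spacing_mm
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    centers: list[np.ndarray] = []
    for i, r in enumerate(radii_mm):
        margin = r * 1.2 + 2.0 * max(spacing)
        lo, hi = margin, extent - margin
        if np.any(lo >= hi):
            raise LesionPlacementError(
                f"grid_shape {shape} too small for lesion_radius_mm ~{r:.1f}"
            )
        semi = 0.45 * extent
        for _ in range(600):
            c = rng.uniform(lo, hi)
            if np.sum(((c - extent / 2) / (0.85 * semi)) ** 2) > 1.0:
                continue
            ok = all(
                np.linalg.norm(c - cj) > 1.3 * (r + rj) + 4.0
                for cj, rj in zip(centers, radii_mm)
            )
            if ok:
                centers.append(c)
                break
        else:
            raise LesionPlacementError(
                f"could not place lesion {i + 1}/{len(radii_mm)}: "
                f"lesion_count={spec.lesion_count} does not fit grid_shape={shape}"
            )
    return np.array(centers)


# ---------------------------------------------------------------------------
# public API


def generate_case(spec: PhantomSpec) -> CaseRecord:
    """Simulate one case; bit-deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.spacing_mm
    brain = _brain_support(shape, spacing)

    for _attempt in range(8):
        # largest lesions placed first: packing succeeds far more often
        radii = np.sort(rng.uniform(*spec.lesion_radius_mm, size=spec.lesion_count))[::-1]
        if spec.tumor_type == GLIOMA and spec.lesion_count > 1:
            # multifocal glioma: satellite lesions are smaller than the primary
            radii[1:] *= 0.5
        edema_margin = rng.uniform(2.0, 5.0, size=spec.lesion_count)
        centers = _place_centers(rng, spec, radii, edema_margin)

        enhancing = np.zeros(shape, dtype=bool)
        edema = np.zeros(shape, dtype=bool)
        for c, r, em in zip(centers, radii, edema_margin):
            les = _lesion_mask(rng, shape, spacing, c, r, spec.shape_irregularity)
            enhancing |= les
            grown = ndimage.distance_transform_edt(~les, sampling=spacing) <= em
            edema |= grown
        enhancing &= brain
        edema &= brain

        labels = np.zeros(shape, dtype=np.int16)
        labels[edema & ~enhancing] = LABEL_EDEMA
        labels[enhancing] = LABEL_ENHANCING
        if spec.tumor_type == GLIOMA:
            depth = ndimage.distance_transform_edt(enhancing, sampling=spacing)
            necrotic = depth > 0.4 * float(np.mean(radii))
            if not necrotic.any():
                necrotic = depth >= 0.8 * float(depth.max())
            labels[necrotic] = LABEL_NECROTIC

        n_found = count_lesions(
            np.isin(labels, (LABEL_ENHANCING, LABEL_NECROTIC)), connectivity=26
        ).lesion_count
        if n_found == spec.lesion_count:
            break
    else:
        raise LesionPlacementError(
            f"lesion_count={spec.lesion_count} could not be realized as distinct "
            f"enhancing components on grid_shape={shape}"
        )

    volumes = {}
    for seq in SEQUENCES:
        means = spec.compartment_contrast[seq]
        img = np.zeros(shape, dtype=np.float64)
        img[brain] = means["background"]
        img[labels == LABEL_EDEMA] = means["edema"]
        img[labels == LABEL_ENHANCING] = means["enhancing"]
        img[labels == LABEL_NECROTIC] = means.get("necrotic", means["enhancing"])
        if spec.noise_sd > 0:
            img[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
        volumes[seq] = Volume(data=img, spacing=spacing)

    mask = SegMask(labels=labels, spacing=spacing)
    return CaseRecord(
        case_id=f"{spec.tumor_type}-{spec.seed}",
        t1ce=volumes["t1ce"],
        t2flair=volumes["flair"],
        truth_mask=mask,
        label=LABEL_OF_TYPE[spec.tumor_type],
        lesion_count_truth=spec.lesion_count,
    )


@dataclass
class CohortRanges:
    """Class-conditional sampling ranges for cohort simulation."""

    glioma_lesion_counts: tuple[int, ...] = (1, 1, 1, 1, 2)
    glioma_radius_mm: tuple[float, float] = (8.0, 15.0)
    glioma_irregularity: tuple[float, float] = (0.3, 0.7)
    mets_lesion_counts: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    mets_radius_mm: tuple[float, float] = (3.0, 7.0)
    mets_irregularity: tuple[float, float] = (0.05, 0.35)
    noise_sd: float = 5.0


def largest_remainder_sizes(n: int, fractions) -> list[int]:
    """Apportion ``n`` items to groups by the largest-remainder method."""
    fractions = np.asarray(fractions, dtype=float)
    quotas = n * fractions / fractions.sum()
    sizes = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - sizes))[: n - sizes.sum()]:
        sizes[i] += 1
    return [int(s) for s in sizes]


def stratified_split(labels, fractions=(0.6, 0.2, 0.2), seed: int = 0) -> list[str]:
    """Assign each case to train/validation/test, stratified by class."""
    labels = np.asarray(labels)
    names = ("train", "validation", "test")
    out = np.empty(len(labels), dtype=object)
    rng = np.random.default_rng(seed)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        sizes = largest_remainder_sizes(len(idx), fractions)
        start = 0
        for name, size in zip(names, sizes):
            out[idx[start : start + size]] = name
            start += size
    return list(out)


def generate_cohort(
    n_glioma: int,
    n_mets: int,
    spec_ranges: CohortRanges | None = None,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (96, 96, 64),
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> tuple[list[CaseRecord], pd.DataFrame]:
    """Simulate a labelled cohort plus a manifest with split assignments."""
    if n_glioma < 0 or n_mets < 0:
        raise ValueError("cohort sizes must be nonnegative")
    ranges = spec_ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    cases: list[CaseRecord] = []
    rows = []
    for i in range(n_glioma + n_mets):
        tumor_type = GLIOMA if i < n_glioma else METS
        case_seed = int(rng.integers(0, 2**31 - 1))
        if tumor_type == GLIOMA:
            counts, radius, irr = (
                ranges.glioma_lesion_counts,
                ranges.glioma_radius_mm,
                ranges.glioma_irregularity,
            )
        else:
            counts, radius, irr = (
                ranges.mets_lesion_counts,
                ranges.mets_radius_mm,
                ranges.mets_irregularity,
            )
        spec = PhantomSpec(
            tumor_type=tumor_type,
            grid_shape=grid_shape,
            spacing_mm=spacing_mm,
            lesion_count=int(rng.choice(counts)),
            lesion_radius_mm=radius,
            shape_irregularity=float(rng.uniform(*irr)),
            noise_sd=ranges.noise_sd,
            seed=case_seed,
        )
        case = generate_case(spec)
        case.case_id = f"case{i:04d}-{tumor_type}"
        cases.append(case)
        rows.append(
            {
                "case_id": case.case_id,
                "label": case.label,
                "seed": case_seed,
                "lesion_count": case.lesion_count_truth,
            }
        )
    manifest = pd.DataFrame(rows)
    if len(manifest):
        manifest["split"] = stratified_split(
            manifest["label"].to_numpy(), split_fractions, seed=seed
        )
    else:
        manifest["split"] = pd.Series(dtype=object)
    return cases, manifest


def mets_style_mask(mask: SegMask) -> SegMask:
    """Project a mask to the two-compartment scheme (necrosis -> enhancing)."""
    labels = np.asarray(mask.labels).copy()
    labels[labels == LABEL_NECROTIC] = LABEL_ENHANCING
    return mask.with_labels(labels)


def corrupt_mask(
    truth: SegMask,
    target_dice: float,
    seed: int = 0,
    max_spurious_voxels: int = 30,
    n_spurious: tuple[int, int] = (1, 3),
) -> SegMask:
    """Degrade a ground-truth mask to a requested whole-ROI Dice.

    Smooth zero-mean noise is added to the signed distance of the whole-ROI
    support and its amplitude bisected until the Dice against truth is within
    +/-0.05 of ``target_dice``; surviving voxels inherit the label of the
    nearest truth voxel, and a few small spurious components (each at most
    ``max_spurious_voxels`` voxels, labels drawn from the truth label set)
    are added away from the lesion.  Deterministic per seed.
    """
    if not (0.0 < target_dice <= 1.0):
        raise ValueError(f"target_dice must lie in (0, 1], got {target_dice}")
    support = whole_roi(truth)
    if not support.any():
        raise ValueError("truth mask is empty")
    if target_dice == 1.0:
        return truth.copy()

    rng = np.random.default_rng(seed)
    spacing = truth.spacing
    signed = ndimage.distance_transform_edt(
        support, sampling=spacing
    ) - ndimage.distance_transform_edt(~support, sampling=spacing)
    noise = ndimage.gaussian_filter(rng.standard_normal(truth.shape), sigma=3.0)
    noise /= max(noise.std(), 1e-12)

    from .roi import dice as _dice  # local import avoids cycle at module load

    def perturbed(amp: float) -> np.ndarray:
        return (signed + amp * noise) > 0

    lo, hi = 0.0, 1.0
    while _dice(support, perturbed(hi)) > target_dice and hi < 1e3:
        hi *= 2.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _dice(support, perturbed(mid)) > target_dice:
            lo = mid
        else:
            hi = mid
    new_support = perturbed(0.5 * (lo + hi))
    if not new_support.any():
        new_support = support.copy()

    # voxels keep/inherit the label of the nearest truth lesion voxel
    _, nearest = ndimage.distance_transform_edt(
        ~support, sampling=spacing, return_indices=True
    )
    labels_src = np.asarray(truth.labels)
    out = np.zeros_like(labels_src)
    out[new_support] = labels_src[tuple(ind[new_support] for ind in nearest)]

    # spurious small components, of a label already present in the truth
    present = [int(v) for v in np.unique(labels_src) if v != 0]
    fill_label = max(present)
    spur_radius_vox = max(1.0, (3.0 * max_spurious_voxels / (4.0 * np.pi)) ** (1 / 3.0))
    shape = truth.shape
    for _ in range(int(rng.integers(n_spurious[0], n_spurious[1] + 1))):
        for _try in range(50):
            c = np.array([rng.integers(2, s - 2) for s in shape])
            if not new_support[tuple(c)]:
                break
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        ball = sum((g - ci) ** 2 for g, ci in zip(grids, c)) <= spur_radius_vox**2
        ball &= out == 0
        if 0 < int(ball.sum()) <= max_spurious_voxels:
            out[ball] = int(rng.choice(present)) if len(present) > 1 else fill_label
    return truth.with_labels(out)
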