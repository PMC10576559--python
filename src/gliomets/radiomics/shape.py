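"""Shape features of the ROI (intensity-independent, computed once per case).

Surface quantities come from a marching-cubes mesh of the binary mask;
axis lengths from a principal-component analysis of physical voxel-center
coordinates; maximum diameters use the voxel-center convention (largest
pairwise Euclidean distance between surface voxel centers).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .registry import SHAPE_FEATURES


class DegenerateROIError(ValueError):
    pass


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume via the divergence theorem (sum of signed tetrahedra)."""
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return abs(float(np.einsum("ij,ij->", a, np.cross(b, c)))) / 6.0


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise distance; convex hull prunes large point sets."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 400:
        try:
            hull = ConvexHull(pts, qhull_options="QJ")
            pts = pts[hull.vertices]
        except QhullError:
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def _surface_voxels(roi: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(roi, ndimage.generate_binary_structure(3, 1))
    surf = roi & ~eroded
    return surf if surf.any() else roi


def shape_features(roi: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """The 14 shape descriptors of a binary ROI (physical units: mm)."""
    roi = np.asarray(roi).astype(bool)
    n = int(roi.sum())
    if n < 2:
        raise DegenerateROIError(f"shape features need an ROI of >= 2 voxels, got {n}")
    spacing = tuple(float(s) for s in spacing)
    voxel_vol = float(np.prod(spacing))

    # a lightly smoothed indicator removes the staircase bias of meshing a
    # raw binary mask (a digital ball would otherwise read ~8% too much
    # surface); thin ROIs that vanish under smoothing fall back to the raw
    # mask, then to voxel approximations (minimum-thickness guard)
    padded = np.pad(roi.astype(np.float64), 2)
    surface_area = mesh_volume = None
    for smooth in (0.8, 0.0):
        field = ndimage.gaussian_filter(padded, smooth) if smooth else padded
        if field.max() <= 0.5:
            continue
        try:
            verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=spacing)
            surface_area = float(measure.mesh_surface_area(verts, faces))
            mesh_volume = _mesh_volume(verts, faces)
            break
        except (ValueError, RuntimeError):
            continue
    if surface_area is None:
        surface_area = 6.0 * n * voxel_vol ** (2.0 / 3.0)
        mesh_volume = n * voxel_vol
    mesh_volume = max(mesh_volume, 1e-9)

    coords_vox = np.argwhere(roi)
    coords = coords_vox * np.asarray(spacing)

    surf_coords = np.argwhere(_surface_voxels(roi)) * np.asarray(spacing)
    max3d = _max_pairwise(surf_coords)

    # per-slice maximum in-plane diameters; plane normal: z (Slice), y
    # (Column), x (Row)
    surf_vox = np.argwhere(_surface_voxels(roi))
    max2d = {}
    for key, axis in (("Slice", 2), ("Column", 1), ("Row", 0)):
        best = 0.0
        for coord in np.unique(surf_vox[:, axis]):
            pts = surf_vox[surf_vox[:, axis] == coord].astype(float) * np.asarray(spacing)
            pts = np.delete(pts, axis, axis=1)
            best = max(best, _max_pairwise(pts))
        max2d[key] = best

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    eig = np.clip(np.sort(np.linalg.eigvalsh(cov))[::-1], 0.0, None)
    major, minor, least = (4.0 * np.sqrt(lam) for lam in eig)
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area

    values = {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n * voxel_vol,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d["Slice"],
        "Maximum2DDiameterColumn": max2d["Column"],
        "Maximum2DDiameterRow": max2d["Row"],
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": elongation,
        "Flatness": flatness,
    }
    assert tuple(values) == SHAPE_FEATURES
    return values
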