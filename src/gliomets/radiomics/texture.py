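"""Texture matrices and their features.

Four gray-level matrices summarize spatial intensity patterns of the
discretized ROI:

* GLCM — co-occurrence of gray-level pairs at distance 1 over the 13 unique
  3D directions; the matrix is symmetrized and features are averaged over
  directions (22 features).
* GLRLM — run lengths of equal gray level along the same 13 directions,
  features averaged over directions (16 features).
* GLSZM — sizes of 26-connected zones of equal gray level (16 features).
* GLDM — dependence counts: 1 + number of equal-gray 26-neighbors inside
  the ROI (14 features).

All matrices are built by vectorized counting; run lengths use pointer
doubling so the cost is O(n log max_run) per direction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .registry import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
)

_EPS = np.finfo(np.float64).tiny

#: the 13 unique (up to sign) nearest-neighbor 3D directions
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


def _shift(arr: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """Return array with contents translated by +d (out-of-grid -> fill)."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, di in zip(arr.shape, d):
        src.append(slice(max(0, -di), n - max(0, di)))
        dst.append(slice(max(0, di), n - max(0, -di)))
    if all(s.start < s.stop for s in dst):
        out[tuple(dst)] = arr[tuple(src)]
    return out


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(bins: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction (Ng x Ng)."""
    shifted = _shift(bins, direction, fill=0)
    valid = (bins > 0) & (shifted > 0)
    a = bins[valid] - 1
    b = shifted[valid] - 1
    counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
    mat = counts.reshape(n_levels, n_levels).astype(np.float64)
    return mat + mat.T


def glcm_features_single(p: np.ndarray) -> dict[str, float]:
    """The 22 GLCM features of one normalized co-occurrence matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.abs(ii - jj).astype(int)
    p_diff = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=ng)
    kd = np.arange(ng, dtype=np.float64)
    k_sum = (ii + jj).astype(int)
    p_sum = np.bincount(k_sum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    diff_avg = float(np.sum(kd * p_diff))

    hx = _entropy2(px)
    hy = _entropy2(py)
    hxy = _entropy2(p.ravel())
    outer = np.outer(px, py)
    pos = p > 0
    hxy1 = float(-np.sum(p[pos] * np.log2(outer[pos] + _EPS)))
    pos_o = outer > 0
    hxy2 = float(-np.sum(outer[pos_o] * np.log2(outer[pos_o])))

    if sd_x * sd_y > 0:
        correlation = (float(np.sum(ii * jj * p)) - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 1.0
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = k_diff > 0
    inverse_variance = float(np.sum(p[off] / (ii - jj)[off] ** 2))

    values = {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "JointAverage": mu_x,
        "ClusterProminence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - mu_x - mu_y) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float(np.sum((kd - diff_avg) ** 2 * p_diff)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) ** 2) / ng**2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inverse_variance,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": float(np.sum((ii - mu_x) ** 2 * p)),
    }
    assert tuple(values) == GLCM_FEATURES
    return values


def glcm_features(bins: np.ndarray, n_levels: int) -> dict[str, float]:
    """Direction-averaged GLCM features."""
    acc: dict[str, float] = dict.fromkeys(GLCM_FEATURES, 0.0)
    n_used = 0
    for d in DIRECTIONS_13:
        mat = glcm_matrix(bins, n_levels, d)
        total = mat.sum()
        if total == 0:
            continue
        feats = glcm_features_single(mat / total)
        for k, v in feats.items():
            acc[k] += v
        n_used += 1
    if n_used == 0:
        raise ValueError("no valid voxel pairs for GLCM (ROI too small)")
    return {k: v / n_used for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM


def _run_lengths(bins: np.ndarray, direction) -> tuple[np.ndarray, np.ndarray]:
    """Gray level and run length of each run start along one direction."""
    inside = bins > 0
    nxt = _shift(bins, tuple(-d for d in direction), fill=0)
    cont = inside & (nxt == bins)  # voxel continues into the next one

    length = np.ones(bins.shape, dtype=np.int64)
    length[~inside] = 0
    reach = cont.copy()
    jump = 1
    while reach.any():
        step = tuple(-d * jump for d in direction)
        length = length + np.where(reach, _shift(length, step, fill=0), 0)
        reach = reach & _shift(reach, step, fill=False)
        jump *= 2

    prv = _shift(bins, direction, fill=0)
    starts = inside & (prv != bins)
    return bins[starts], length[starts]


def glrlm_matrix(bins: np.ndarray, n_levels: int, direction) -> np.ndarray:
    grays, lengths = _run_lengths(bins, direction)
    if grays.size == 0:
        return np.zeros((n_levels, 1))
    max_len = int(lengths.max())
    counts = np.bincount(
        (grays - 1) * max_len + (lengths - 1), minlength=n_levels * max_len
    )
    return counts.reshape(n_levels, max_len).astype(np.float64)


def _rl_style_features(mat: np.ndarray, n_voxels: int, names) -> dict:
    """Shared run-length / size-zone feature formulas.

    ``mat[g-1, l-1]`` counts runs (zones) of gray level g and length (size)
    l; the two families share their 16 formulas up to naming.
    """
    ng, nl = mat.shape
    g = np.arange(1, ng + 1, dtype=np.float64)
    l = np.arange(1, nl + 1, dtype=np.float64)
    gg, ll = np.meshgrid(g, l, indexing="ij")
    n_runs = mat.sum()
    if n_runs == 0:
        raise ValueError("empty run/zone matrix")
    p = mat / n_runs
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_g = float(np.sum(g * pg))
    mu_l = float(np.sum(l * pl))

    vals = [
        float(np.sum(p / ll**2)),  # short/small emphasis
        float(np.sum(p * ll**2)),  # long/large emphasis
        float(np.sum(mat.sum(axis=1) ** 2) / n_runs),  # GLN
        float(np.sum(pg**2)),  # GLNN
        float(np.sum(mat.sum(axis=0) ** 2) / n_runs),  # RLN / SZN
        float(np.sum(pl**2)),  # RLNN / SZNN
        float(n_runs / n_voxels),  # run/zone percentage
        float(np.sum(p * (gg - mu_g) ** 2)),  # gray level variance
        float(np.sum(p * (ll - mu_l) ** 2)),  # run/zone variance
        _entropy2(p.ravel()),  # run/zone entropy
        float(np.sum(p / gg**2)),  # low gray emphasis
        float(np.sum(p * gg**2)),  # high gray emphasis
        float(np.sum(p / (gg**2 * ll**2))),
        float(np.sum(p * gg**2 / ll**2)),
        float(np.sum(p * ll**2 / gg**2)),
        float(np.sum(p * gg**2 * ll**2)),
    ]
    return dict(zip(names, vals))


def glrlm_features(bins: np.ndarray, n_levels: int) -> dict[str, float]:
    """Direction-averaged GLRLM features."""
    n_voxels = int((bins > 0).sum())
    acc: dict[str, float] = dict.fromkeys(GLRLM_FEATURES, 0.0)
    n_used = 0
    for d in DIRECTIONS_13:
        mat = glrlm_matrix(bins, n_levels, d)
        if mat.sum() == 0:
            continue
        feats = _rl_style_features(mat, n_voxels, GLRLM_FEATURES)
        for k, v in feats.items():
            acc[k] += v
        n_used += 1
    if n_used == 0:
        raise ValueError("no runs found for GLRLM")
    return {k: v / n_used for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(bins: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts: 26-connected zones of equal gray level."""
    structure = ndimage.generate_binary_structure(3, 3)
    zone_sizes: list[tuple[int, int]] = []
    for g in range(1, n_levels + 1):
        level = bins == g
        if not level.any():
            continue
        labeled, n = ndimage.label(level, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        zone_sizes.extend((g, int(s)) for s in sizes)
    if not zone_sizes:
        return np.zeros((n_levels, 1))
    max_size = max(s for _, s in zone_sizes)
    mat = np.zeros((n_levels, max_size))
    for g, s in zone_sizes:
        mat[g - 1, s - 1] += 1
    return mat


def glszm_features(bins: np.ndarray, n_levels: int) -> dict[str, float]:
    n_voxels = int((bins > 0).sum())
    mat = glszm_matrix(bins, n_levels)
    return _rl_style_features(mat, n_voxels, GLSZM_FEATURES)


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(bins: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts: mat[g-1, k-1] = #voxels of gray g whose
    dependence (1 + equal-gray 26-neighbors in the ROI) equals k."""
    inside = bins > 0
    dep = np.ones(bins.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        for sign in (1, -1):
            off = tuple(sign * di for di in d)
            dep += (inside & (_shift(bins, off, fill=0) == bins)).astype(np.int64)
    grays = bins[inside]
    deps = dep[inside]
    max_dep = int(deps.max())
    counts = np.bincount(
        (grays - 1) * max_dep + (deps - 1), minlength=n_levels * max_dep
    )
    return counts.reshape(n_levels, max_dep).astype(np.float64)


def gldm_features(bins: np.ndarray, n_levels: int) -> dict[str, float]:
    return _gldm_features_from_matrix(gldm_matrix(bins, n_levels))


def _gldm_features_from_matrix(mat: np.ndarray) -> dict[str, float]:
    ng, nd = mat.shape
    g = np.arange(1, ng + 1, dtype=np.float64)
    k = np.arange(1, nd + 1, dtype=np.float64)
    gg, kk = np.meshgrid(g, k, indexing="ij")
    nz = mat.sum()
    if nz == 0:
        raise ValueError("empty dependence matrix")
    p = mat / nz
    pg = p.sum(axis=1)
    pk = p.sum(axis=0)
    mu_g = float(np.sum(g * pg))
    mu_k = float(np.sum(k * pk))
    values = {
        "SmallDependenceEmphasis": float(np.sum(p / kk**2)),
        "LargeDependenceEmphasis": float(np.sum(p * kk**2)),
        "GrayLevelNonUniformity": float(np.sum(mat.sum(axis=1) ** 2) / nz),
        "DependenceNonUniformity": float(np.sum(mat.sum(axis=0) ** 2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pk**2)),
        "GrayLevelVariance": float(np.sum(p * (gg - mu_g) ** 2)),
        "DependenceVariance": float(np.sum(p * (kk - mu_k) ** 2)),
        "DependenceEntropy": _entropy2(p.ravel()),
        "LowGrayLevelEmphasis": float(np.sum(p / gg**2)),
        "HighGrayLevelEmphasis": float(np.sum(p * gg**2)),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(p / (gg**2 * kk**2))),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(p * gg**2 / kk**2)),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(p * kk**2 / gg**2)),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(p * gg**2 * kk**2)),
    }
    assert tuple(values) == GLDM_FEATURES
    return values


def _pad_to(mat: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape)
    out[: mat.shape[0], : mat.shape[1]] = mat
    return out


def _accumulate(mats: list[np.ndarray]) -> np.ndarray:
    cols = max(m.shape[1] for m in mats)
    total = np.zeros((mats[0].shape[0], cols))
    for m in mats:
        total[:, : m.shape[1]] += m
    return total


def texture_features(bins: np.ndarray, n_levels: int) -> dict[str, dict[str, float]]:
    """All four texture families of one discretized image (68 values).

    No gray-level matrix entry can cross a whole-ROI connected component
    (background interrupts pairs, runs, zones and dependences), so the
    matrices are accumulated per component on tight per-component boxes —
    a large speed-up for multi-lesion masks — and the features are then
    computed from the combined matrices.
    """
    roi = bins > 0
    n_voxels = int(roi.sum())
    if n_voxels < 2:
        raise ValueError("texture features need an ROI of >= 2 voxels")

    labeled, n_comp = ndimage.label(roi, structure=ndimage.generate_binary_structure(3, 3))
    if n_comp <= 1:
        parts = [np.asarray(bins)]
    else:
        parts = []
        for i, box in enumerate(ndimage.find_objects(labeled), start=1):
            sub = np.where(labeled[box] == i, bins[box], 0)
            parts.append(sub)

    glcm_mats = [
        _accumulate([glcm_matrix(p, n_levels, d) for p in parts]) for d in DIRECTIONS_13
    ]
    glrlm_mats = [
        _accumulate([glrlm_matrix(p, n_levels, d) for p in parts]) for d in DIRECTIONS_13
    ]
    glszm_mat = _accumulate([glszm_matrix(p, n_levels) for p in parts])
    gldm_mat = _accumulate([gldm_matrix(p, n_levels) for p in parts])

    glcm_acc = dict.fromkeys(GLCM_FEATURES, 0.0)
    glrlm_acc = dict.fromkeys(GLRLM_FEATURES, 0.0)
    n_glcm = n_glrlm = 0
    for mat in glcm_mats:
        total = mat.sum()
        if total == 0:
            continue
        for k, v in glcm_features_single(mat / total).items():
            glcm_acc[k] += v
        n_glcm += 1
    for mat in glrlm_mats:
        if mat.sum() == 0:
            continue
        for k, v in _rl_style_features(mat, n_voxels, GLRLM_FEATURES).items():
            glrlm_acc[k] += v
        n_glrlm += 1
    if n_glcm == 0 or n_glrlm == 0:
        raise ValueError("no valid voxel pairs for texture matrices (ROI too small)")

    return {
        "glcm": {k: v / n_glcm for k, v in glcm_acc.items()},
        "gldm": _gldm_features_from_matrix(gldm_mat),
        "glrlm": {k: v / n_glrlm for k, v in glrlm_acc.items()},
        "glszm": _rl_style_features(glszm_mat, n_voxels, GLSZM_FEATURES),
    }
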