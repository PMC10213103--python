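"""Gray-level texture matrices and their features.

All five families operate on a 3-D integer level volume where 0 marks voxels
outside the ROI and 1..Ng are the discretised gray levels.  The neighbourhood
is the full 26-connectivity; GLCM and GLRLM accumulate over the 13 unique
direction vectors and average *feature values* across directions (matrices
are not merged).  Formulas follow the IBSI / fixed-bin-width extraction
convention; degenerate definitions (division by zero on single-level ROIs)
return the documented sentinels: 0.0, except Coarseness (capped at 1e6 when
its denominator vanishes) and MCC (1.0 on a single-level ROI).
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from ..imaging import DiscretizedROI, ROIMask, mask_bounding_box

COARSENESS_CAP = 1.0e6
_EPS = np.finfo(np.float64).eps

# 13 unique direction vectors of the 26-neighbourhood (first non-zero positive)
DIRECTIONS_13: list[tuple[int, int, int]] = [
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0) and d > (0, 0, 0)
]
OFFSETS_26: list[tuple[int, int, int]] = [
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]


def level_volume(mask: ROIMask, discretized: DiscretizedROI) -> np.ndarray:
    """Bounding-box level volume: 0 outside the ROI, 1..Ng inside."""
    box = mask_bounding_box(mask)
    sub = mask.values[box]
    out = np.zeros(sub.shape, dtype=np.int64)
    out[sub] = discretized.levels
    return out


def _pair_slices(shape, offset):
    """Slices (src, dst) such that arr[dst] sits at arr[src] + offset."""
    src, dst = [], []
    for o, n in zip(offset, shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def glcm_matrices(levels: np.ndarray, n_levels: int, distance: int = 1) -> list[np.ndarray]:
    """Symmetric, normalised co-occurrence matrix per direction."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    mats = []
    for d in DIRECTIONS_13:
        off = tuple(distance * o for o in d)
        src, dst = _pair_slices(levels.shape, off)
        a = levels[src].ravel()
        b = levels[dst].ravel()
        valid = (a > 0) & (b > 0)
        counts = np.bincount(
            (a[valid] - 1) * n_levels + (b[valid] - 1), minlength=n_levels * n_levels
        ).reshape(n_levels, n_levels).astype(np.float64)
        sym = counts + counts.T
        total = sym.sum()
        mats.append(sym / total if total > 0 else sym)
    return mats


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii = i[:, None]
    jj = i[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)  # == px for symmetric P
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    var_x = float(np.sum(px * (i - mu_x) ** 2))
    var_y = float(np.sum(py * (i - mu_y) ** 2))

    k_diff = np.arange(ng, dtype=np.float64)  # |i-j| = 0..ng-1
    absdiff = np.abs(ii - jj).astype(np.int64)
    sums = (ii + jj).astype(np.int64)
    p_diff = np.bincount(absdiff.ravel(), weights=P.ravel(), minlength=ng)
    p_sum = np.bincount((sums - 2).ravel(), weights=P.ravel(), minlength=2 * ng - 1)

    def ent(p):
        p = p[p > 0]
        return float(-np.sum(p * np.log2(p))) if p.size else 0.0

    hxy = ent(P.ravel())
    hx = ent(px)
    hy = ent(py)
    pxpy = px[:, None] * py[None, :]
    nz = (P > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(P[nz] * np.log2(pxpy[nz])))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2])))

    diff_avg = float(np.sum(p_diff * k_diff))
    contrast = float(np.sum(P * (ii - jj) ** 2))
    autoc = float(np.sum(P * ii * jj))

    if var_x > 0 and var_y > 0:
        correlation = (autoc - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 0.0

    denom_imc1 = max(hx, hy)
    imc1 = (hxy - hxy1) / denom_imc1 if denom_imc1 > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    offdiag = absdiff > 0
    inv_var = float(np.sum(P[offdiag] / (ii - jj)[offdiag] ** 2)) if offdiag.any() else 0.0

    if ng > 1:
        present = px > 0
        if present.sum() > 1:
            Pp = P[np.ix_(present, present)]
            pxp = px[present]
            pyp = py[present]
            # Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) py(k)), as a matrix product
            Q = (Pp / pxp[:, None]) @ (Pp / pyp[None, :]).T
            eig = np.sort(np.real(np.linalg.eigvals(Q)))
            mcc = float(np.sqrt(max(0.0, min(1.0, eig[-2])))) if eig.size > 1 else 1.0
        else:
            mcc = 1.0
    else:
        mcc = 1.0

    return {
        "Autocorrelation": autoc,
        "ClusterProminence": float(np.sum(P * (ii + jj - mu_x - mu_y) ** 4)),
        "ClusterShade": float(np.sum(P * (ii + jj - mu_x - mu_y) ** 3)),
        "ClusterTendency": float(np.sum(P * (ii + jj - mu_x - mu_y) ** 2)),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(np.sum(p_diff * (k_diff - diff_avg) ** 2)),
        "Id": float(np.sum(P / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(P / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(P / (1.0 + ((ii - jj) ** 2) / ng**2))),
        "Idn": float(np.sum(P / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumEntropy": ent(p_sum),
        "SumSquares": var_x,
    }


def compute_glcm_features(levels: np.ndarray, n_levels: int, distance: int = 1) -> dict[str, float]:
    """GLCM features averaged over the 13 unique 3-D directions."""
    if levels.max() == 0:
        raise ValueError("empty ROI")
    mats = glcm_matrices(levels, n_levels, distance)
    per_dir = [_glcm_features_single(P) for P in mats if P.sum() > 0]
    if not per_dir:
        raise ValueError("no valid voxel pairs at the requested distance")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

def glrlm_matrix(levels: np.ndarray, n_levels: int, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length matrix R[g-1, l-1] of maximal runs along one direction."""
    shape = levels.shape
    src, dst = _pair_slices(shape, direction)
    inside = levels > 0

    prev_same = np.zeros(shape, dtype=bool)
    prev_same[dst] = inside[dst] & (levels[dst] == levels[src])
    next_same = np.zeros(shape, dtype=bool)
    next_same[src] = inside[src] & (levels[src] == levels[dst])

    # run length ending at each voxel: iterate r[v] = r[v - d] + 1 where the
    # predecessor matches; converges in (longest run) sweeps
    run = inside.astype(np.int64)
    max_iter = int(np.max(shape))
    for _ in range(max_iter):
        shifted = np.zeros(shape, dtype=np.int64)
        shifted[dst] = run[src]
        new = np.where(prev_same, shifted + 1, inside.astype(np.int64))
        if np.array_equal(new, run):
            break
        run = new

    ends = inside & ~next_same
    g = levels[ends] - 1
    l = run[ends] - 1
    max_len = int(run.max()) if run.size else 1
    mat = np.zeros((n_levels, max_len), dtype=np.float64)
    np.add.at(mat, (g, l), 1.0)
    return mat


def _rl_style_features(M: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared formula block for GLRLM ('run') and GLSZM ('zone') matrices."""
    nr = M.sum()
    g = np.arange(1, M.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, M.shape[1] + 1, dtype=np.float64)[None, :]
    p = M / nr
    mu_g = float(np.sum(p * g))
    mu_s = float(np.sum(p * s))
    pz = p[p > 0]
    marg_g = M.sum(axis=1)
    marg_s = M.sum(axis=0)

    out = {
        "GrayLevelNonUniformity": float(np.sum(marg_g**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(marg_g**2) / nr**2),
        "GrayLevelVariance": float(np.sum(p * (g - mu_g) ** 2)),
    }
    if kind == "run":
        out.update({
            "HighGrayLevelRunEmphasis": float(np.sum(M * g**2) / nr),
            "LongRunEmphasis": float(np.sum(M * s**2) / nr),
            "LongRunHighGrayLevelEmphasis": float(np.sum(M * g**2 * s**2) / nr),
            "LongRunLowGrayLevelEmphasis": float(np.sum(M * s**2 / g**2) / nr),
            "LowGrayLevelRunEmphasis": float(np.sum(M / g**2) / nr),
            "RunEntropy": float(-np.sum(pz * np.log2(pz))),
            "RunLengthNonUniformity": float(np.sum(marg_s**2) / nr),
            "RunLengthNonUniformityNormalized": float(np.sum(marg_s**2) / nr**2),
            "RunPercentage": float(nr / n_voxels),
            "RunVariance": float(np.sum(p * (s - mu_s) ** 2)),
            "ShortRunEmphasis": float(np.sum(M / s**2) / nr),
            "ShortRunHighGrayLevelEmphasis": float(np.sum(M * g**2 / s**2) / nr),
            "ShortRunLowGrayLevelEmphasis": float(np.sum(M / (g**2 * s**2)) / nr),
        })
    else:
        out.update({
            "HighGrayLevelZoneEmphasis": float(np.sum(M * g**2) / nr),
            "LargeAreaEmphasis": float(np.sum(M * s**2) / nr),
            "LargeAreaHighGrayLevelEmphasis": float(np.sum(M * g**2 * s**2) / nr),
            "LargeAreaLowGrayLevelEmphasis": float(np.sum(M * s**2 / g**2) / nr),
            "LowGrayLevelZoneEmphasis": float(np.sum(M / g**2) / nr),
            "ZoneEntropy": float(-np.sum(pz * np.log2(pz))),
            "SizeZoneNonUniformity": float(np.sum(marg_s**2) / nr),
            "SizeZoneNonUniformityNormalized": float(np.sum(marg_s**2) / nr**2),
            "ZonePercentage": float(nr / n_voxels),
            "ZoneVariance": float(np.sum(p * (s - mu_s) ** 2)),
            "SmallAreaEmphasis": float(np.sum(M / s**2) / nr),
            "SmallAreaHighGrayLevelEmphasis": float(np.sum(M * g**2 / s**2) / nr),
            "SmallAreaLowGrayLevelEmphasis": float(np.sum(M / (g**2 * s**2)) / nr),
        })
    return out


def compute_glrlm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """GLRLM features averaged over the 13 unique 3-D directions."""
    n_voxels = int((levels > 0).sum())
    if n_voxels == 0:
        raise ValueError("empty ROI")
    per_dir = [
        _rl_style_features(glrlm_matrix(levels, n_levels, d), n_voxels, "run")
        for d in DIRECTIONS_13
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------------------
# GLSZM
# --------------------------------------------------------------------------

def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix Z[g-1, s-1]: zones are 26-connected equal-level components."""
    zones: list[tuple[int, int]] = []
    for gl in np.unique(levels[levels > 0]):
        lab, n_comp = cc_label(levels == gl, connectivity=3, return_num=True)
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            zones.append((int(gl), int(sz)))
    max_size = max(sz for _, sz in zones)
    mat = np.zeros((n_levels, max_size), dtype=np.float64)
    for gl, sz in zones:
        mat[gl - 1, sz - 1] += 1.0
    return mat


def compute_glszm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    n_voxels = int((levels > 0).sum())
    if n_voxels == 0:
        raise ValueError("empty ROI")
    return _rl_style_features(glszm_matrix(levels, n_levels), n_voxels, "zone")


# --------------------------------------------------------------------------
# GLDM
# --------------------------------------------------------------------------

def gldm_dependence(levels: np.ndarray, alpha: float = 0.0) -> np.ndarray:
    """Per-voxel dependence: count of 26-neighbours within alpha of the level."""
    inside = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        src, dst = _pair_slices(levels.shape, off)
        dep[dst] += (
            inside[dst] & inside[src] & (np.abs(levels[dst] - levels[src]) <= alpha)
        )
    dep[~inside] = 0
    return dep


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: float = 0.0) -> np.ndarray:
    """Dependence matrix D[g-1, d]: columns indexed by dependence count 0..26."""
    inside = levels > 0
    dep = gldm_dependence(levels, alpha)
    g = levels[inside] - 1
    d = dep[inside]
    max_dep = int(d.max())
    mat = np.zeros((n_levels, max_dep + 1), dtype=np.float64)
    np.add.at(mat, (g, d), 1.0)
    return mat


def compute_gldm_features(levels: np.ndarray, n_levels: int, alpha: float = 0.0) -> dict[str, float]:
    """GLDM features; dependence size j = neighbour count + 1 (centre counted)."""
    n_voxels = int((levels > 0).sum())
    if n_voxels == 0:
        raise ValueError("empty ROI")
    M = gldm_matrix(levels, n_levels, alpha)
    nz = M.sum()
    g = np.arange(1, M.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, M.shape[1] + 1, dtype=np.float64)[None, :]  # dependence size
    p = M / nz
    mu_j = float(np.sum(p * j))
    mu_g = float(np.sum(p * g))
    pz = p[p > 0]
    marg_g = M.sum(axis=1)
    marg_j = M.sum(axis=0)
    return {
        "DependenceEntropy": float(-np.sum(pz * np.log2(pz))),
        "DependenceNonUniformity": float(np.sum(marg_j**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(marg_j**2) / nz**2),
        "DependenceVariance": float(np.sum(p * (j - mu_j) ** 2)),
        "GrayLevelNonUniformity": float(np.sum(marg_g**2) / nz),
        "GrayLevelVariance": float(np.sum(p * (g - mu_g) ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(M * g**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(M * j**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(M * g**2 * j**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(M * j**2 / g**2) / nz),
        "LowGrayLevelEmphasis": float(np.sum(M / g**2) / nz),
        "SmallDependenceEmphasis": float(np.sum(M / j**2) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(M * g**2 / j**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(M / (g**2 * j**2)) / nz),
    }


# --------------------------------------------------------------------------
# NGTDM
# --------------------------------------------------------------------------

def ngtdm_table(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts n_i and summed neighbourhood differences s_i.

    For each ROI voxel with at least one in-ROI 26-neighbour, the absolute
    difference between its level and the mean level of those neighbours is
    accumulated into s at its level.  Returns (n, s) indexed by level 1..Ng
    at positions 0..Ng-1.
    """
    inside = levels > 0
    nbr_sum = np.zeros(levels.shape, dtype=np.float64)
    nbr_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        src, dst = _pair_slices(levels.shape, off)
        add = inside[src].astype(np.float64)
        nbr_sum[dst] += levels[src] * add
        nbr_cnt[dst] += inside[src]
    valid = inside & (nbr_cnt > 0)
    diff = np.zeros(levels.shape, dtype=np.float64)
    diff[valid] = np.abs(levels[valid] - nbr_sum[valid] / nbr_cnt[valid])
    n = np.bincount(levels[valid] - 1, minlength=n_levels).astype(np.float64)
    s = np.zeros(n_levels, dtype=np.float64)
    np.add.at(s, levels[valid] - 1, diff[valid])
    return n, s


def compute_ngtdm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    if (levels > 0).sum() == 0:
        raise ValueError("empty ROI")
    n, s = ngtdm_table(levels, n_levels)
    nv = n.sum()
    if nv == 0:
        raise ValueError("no ROI voxel has an in-ROI neighbour")
    p = n / nv
    i = np.arange(1, n_levels + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())

    ps = float(np.sum(p * s))
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    ip = i[present]
    pp = p[present]
    sp = s[present]
    di = ip[:, None] - ip[None, :]

    if ngp > 1:
        contrast = (
            float(np.sum(pp[:, None] * pp[None, :] * di**2)) / (ngp * (ngp - 1))
        ) * (float(s.sum()) / nv)
        denom_busy = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        complexity = float(
            np.sum(
                np.abs(di)
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / (pp[:, None] + pp[None, :])
            )
        ) / nv
        ssum = float(s.sum())
        strength = (
            float(np.sum((pp[:, None] + pp[None, :]) * di**2)) / ssum if ssum > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
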