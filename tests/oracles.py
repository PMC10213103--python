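"""Independent brute-force oracles for the texture-matrix features.

Everything here is written as plainly as possible — explicit Python loops
over voxels, pairs, runs, zones and neighbourhoods — deliberately sharing no
code with the package implementation.  Sentinel conventions for degenerate
definitions follow the package's documented contract (0.0 sentinels,
Coarseness cap 1e6, MCC = 1 on single-level regions).
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

DIRS_13 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0) and d > (0, 0, 0)]
OFFS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
COARSENESS_CAP = 1.0e6


def _inside(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def _roi_voxels(lev):
    return [tuple(v) for v in np.argwhere(lev > 0)]


# ---------------------------------------------------------------- GLCM ----

def bf_glcm_matrix(lev, ng, direction, distance=1):
    P = np.zeros((ng, ng))
    off = tuple(distance * o for o in direction)
    for v in _roi_voxels(lev):
        w = tuple(v[a] + off[a] for a in range(3))
        if _inside(lev.shape, w) and lev[w] > 0:
            P[lev[tuple(v)] - 1, lev[w] - 1] += 1
    P = P + P.T
    tot = P.sum()
    return P / tot if tot > 0 else P


def bf_glcm_features(lev, ng, distance=1):
    per_dir = []
    for d in DIRS_13:
        P = bf_glcm_matrix(lev, ng, d, distance)
        if P.sum() == 0:
            continue
        per_dir.append(_bf_glcm_one(P, ng))
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}


def _bf_glcm_one(P, ng):
    i_vals = list(range(1, ng + 1))
    px = [sum(P[i - 1, j - 1] for j in i_vals) for i in i_vals]
    py = [sum(P[i - 1, j - 1] for i in i_vals) for j in i_vals]
    mu_x = sum(i * px[i - 1] for i in i_vals)
    mu_y = sum(j * py[j - 1] for j in i_vals)
    var_x = sum(px[i - 1] * (i - mu_x) ** 2 for i in i_vals)
    var_y = sum(py[j - 1] * (j - mu_y) ** 2 for j in i_vals)

    p_diff = {}
    p_sum = {}
    for i in i_vals:
        for j in i_vals:
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i - 1, j - 1]
            p_sum[i + j] = p_sum.get(i + j, 0.0) + P[i - 1, j - 1]

    def H(ps):
        return -sum(p * math.log2(p) for p in ps if p > 0)

    hxy = H(P.ravel())
    hx, hy = H(px), H(py)
    hxy1 = -sum(
        P[i - 1, j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in i_vals for j in i_vals
        if P[i - 1, j - 1] > 0 and px[i - 1] * py[j - 1] > 0
    )
    hxy2 = -sum(
        px[i - 1] * py[j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in i_vals for j in i_vals
        if px[i - 1] * py[j - 1] > 0
    )
    da = sum(k * p for k, p in p_diff.items())
    autoc = sum(P[i - 1, j - 1] * i * j for i in i_vals for j in i_vals)

    present = [i for i in i_vals if px[i - 1] > 0]
    if ng > 1 and len(present) > 1:
        q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(
                    P[i - 1, k - 1] * P[j - 1, k - 1] / (px[i - 1] * py[k - 1])
                    for k in i_vals if py[k - 1] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, min(1.0, eig[-2]))) if len(eig) > 1 else 1.0
    else:
        mcc = 1.0

    maxhxhy = max(hx, hy)
    feats = {
        "Autocorrelation": autoc,
        "ClusterProminence": sum(P[i - 1, j - 1] * (i + j - mu_x - mu_y) ** 4 for i in i_vals for j in i_vals),
        "ClusterShade": sum(P[i - 1, j - 1] * (i + j - mu_x - mu_y) ** 3 for i in i_vals for j in i_vals),
        "ClusterTendency": sum(P[i - 1, j - 1] * (i + j - mu_x - mu_y) ** 2 for i in i_vals for j in i_vals),
        "Contrast": sum(P[i - 1, j - 1] * (i - j) ** 2 for i in i_vals for j in i_vals),
        "Correlation": (autoc - mu_x * mu_y) / math.sqrt(var_x * var_y) if var_x > 0 and var_y > 0 else 0.0,
        "DifferenceAverage": da,
        "DifferenceEntropy": H(p_diff.values()),
        "DifferenceVariance": sum(p * (k - da) ** 2 for k, p in p_diff.items()),
        "Id": sum(P[i - 1, j - 1] / (1 + abs(i - j)) for i in i_vals for j in i_vals),
        "Idm": sum(P[i - 1, j - 1] / (1 + (i - j) ** 2) for i in i_vals for j in i_vals),
        "Idmn": sum(P[i - 1, j - 1] / (1 + (i - j) ** 2 / ng**2) for i in i_vals for j in i_vals),
        "Idn": sum(P[i - 1, j - 1] / (1 + abs(i - j) / ng) for i in i_vals for j in i_vals),
        "Imc1": (hxy - hxy1) / maxhxhy if maxhxhy > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
        "InverseVariance": sum(
            P[i - 1, j - 1] / (i - j) ** 2 for i in i_vals for j in i_vals if i != j
        ),
        "JointAverage": mu_x,
        "JointEnergy": sum(P[i - 1, j - 1] ** 2 for i in i_vals for j in i_vals),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": P.max(),
        "SumEntropy": H(p_sum.values()),
        "SumSquares": var_x,
    }
    return feats


# --------------------------------------------------------------- GLRLM ----

def bf_glrlm_matrix(lev, ng, direction):
    runs = []
    for v in _roi_voxels(lev):
        prev = tuple(v[a] - direction[a] for a in range(3))
        if _inside(lev.shape, prev) and lev[prev] == lev[tuple(v)]:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = tuple(cur[a] + direction[a] for a in range(3))
            if _inside(lev.shape, nxt) and lev[nxt] == lev[tuple(v)]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((lev[tuple(v)], length))
    max_len = max(l for _, l in runs)
    M = np.zeros((ng, max_len))
    for g, l in runs:
        M[g - 1, l - 1] += 1
    return M


def _bf_rl_features(M, n_vox, names):
    nr = M.sum()
    ng, nl = M.shape
    feats = {}
    marg_g = M.sum(axis=1)
    marg_s = M.sum(axis=0)
    p = M / nr
    mu_g = sum(g * p[g - 1, s - 1] for g in range(1, ng + 1) for s in range(1, nl + 1))
    mu_s = sum(s * p[g - 1, s - 1] for g in range(1, ng + 1) for s in range(1, nl + 1))
    ent = -sum(x * math.log2(x) for x in p.ravel() if x > 0)

    def S(f):
        return sum(f(g, s) * M[g - 1, s - 1] for g in range(1, ng + 1) for s in range(1, nl + 1)) / nr

    vals = {
        "sre": S(lambda g, s: 1 / s**2),
        "lre": S(lambda g, s: s**2),
        "gln": sum(m**2 for m in marg_g) / nr,
        "glnn": sum(m**2 for m in marg_g) / nr**2,
        "rln": sum(m**2 for m in marg_s) / nr,
        "rlnn": sum(m**2 for m in marg_s) / nr**2,
        "rp": nr / n_vox,
        "glv": sum(p[g - 1, s - 1] * (g - mu_g) ** 2 for g in range(1, ng + 1) for s in range(1, nl + 1)),
        "rv": sum(p[g - 1, s - 1] * (s - mu_s) ** 2 for g in range(1, ng + 1) for s in range(1, nl + 1)),
        "re": ent,
        "lgl": S(lambda g, s: 1 / g**2),
        "hgl": S(lambda g, s: g**2),
        "srlgl": S(lambda g, s: 1 / (g**2 * s**2)),
        "srhgl": S(lambda g, s: g**2 / s**2),
        "lrlgl": S(lambda g, s: s**2 / g**2),
        "lrhgl": S(lambda g, s: g**2 * s**2),
    }
    for name, key in names.items():
        feats[name] = vals[key]
    return feats


_RUN_NAMES = {
    "ShortRunEmphasis": "sre", "LongRunEmphasis": "lre",
    "GrayLevelNonUniformity": "gln", "GrayLevelNonUniformityNormalized": "glnn",
    "RunLengthNonUniformity": "rln", "RunLengthNonUniformityNormalized": "rlnn",
    "RunPercentage": "rp", "GrayLevelVariance": "glv", "RunVariance": "rv",
    "RunEntropy": "re", "LowGrayLevelRunEmphasis": "lgl", "HighGrayLevelRunEmphasis": "hgl",
    "ShortRunLowGrayLevelEmphasis": "srlgl", "ShortRunHighGrayLevelEmphasis": "srhgl",
    "LongRunLowGrayLevelEmphasis": "lrlgl", "LongRunHighGrayLevelEmphasis": "lrhgl",
}

_ZONE_NAMES = {
    "SmallAreaEmphasis": "sre", "LargeAreaEmphasis": "lre",
    "GrayLevelNonUniformity": "gln", "GrayLevelNonUniformityNormalized": "glnn",
    "SizeZoneNonUniformity": "rln", "SizeZoneNonUniformityNormalized": "rlnn",
    "ZonePercentage": "rp", "GrayLevelVariance": "glv", "ZoneVariance": "rv",
    "ZoneEntropy": "re", "LowGrayLevelZoneEmphasis": "lgl", "HighGrayLevelZoneEmphasis": "hgl",
    "SmallAreaLowGrayLevelEmphasis": "srlgl", "SmallAreaHighGrayLevelEmphasis": "srhgl",
    "LargeAreaLowGrayLevelEmphasis": "lrlgl", "LargeAreaHighGrayLevelEmphasis": "lrhgl",
}


def bf_glrlm_features(lev, ng):
    n_vox = int((lev > 0).sum())
    per_dir = [
        _bf_rl_features(bf_glrlm_matrix(lev, ng, d), n_vox, _RUN_NAMES) for d in DIRS_13
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------- GLSZM ----

def bf_glszm_matrix(lev, ng):
    seen = set()
    zones = []
    for v in _roi_voxels(lev):
        if v in seen:
            continue
        g = lev[v]
        stack = [v]
        seen.add(v)
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFS_26:
                w = tuple(cur[a] + off[a] for a in range(3))
                if w not in seen and _inside(lev.shape, w) and lev[w] == g:
                    seen.add(w)
                    stack.append(w)
        zones.append((g, size))
    max_size = max(s for _, s in zones)
    M = np.zeros((ng, max_size))
    for g, s in zones:
        M[g - 1, s - 1] += 1
    return M


def bf_glszm_features(lev, ng):
    n_vox = int((lev > 0).sum())
    return _bf_rl_features(bf_glszm_matrix(lev, ng), n_vox, _ZONE_NAMES)


# ---------------------------------------------------------------- GLDM ----

def bf_gldm_matrix(lev, ng, alpha=0.0):
    deps = []
    for v in _roi_voxels(lev):
        d = 0
        for off in OFFS_26:
            w = tuple(v[a] + off[a] for a in range(3))
            if _inside(lev.shape, w) and lev[w] > 0 and abs(int(lev[w]) - int(lev[v])) <= alpha:
                d += 1
        deps.append((lev[v], d))
    max_d = max(d for _, d in deps)
    M = np.zeros((ng, max_d + 1))
    for g, d in deps:
        M[g - 1, d] += 1
    return M


def bf_gldm_features(lev, ng, alpha=0.0):
    M = bf_gldm_matrix(lev, ng, alpha)
    nz = M.sum()
    n_g, n_d = M.shape
    p = M / nz
    # dependence size j = neighbour count + 1
    mu_j = sum((d + 1) * p[g - 1, d] for g in range(1, n_g + 1) for d in range(n_d))
    mu_g = sum(g * p[g - 1, d] for g in range(1, n_g + 1) for d in range(n_d))
    marg_g = M.sum(axis=1)
    marg_j = M.sum(axis=0)

    def S(f):
        return sum(f(g, d + 1) * M[g - 1, d] for g in range(1, n_g + 1) for d in range(n_d)) / nz

    return {
        "DependenceEntropy": -sum(x * math.log2(x) for x in p.ravel() if x > 0),
        "DependenceNonUniformity": sum(m**2 for m in marg_j) / nz,
        "DependenceNonUniformityNormalized": sum(m**2 for m in marg_j) / nz**2,
        "DependenceVariance": sum(
            p[g - 1, d] * (d + 1 - mu_j) ** 2 for g in range(1, n_g + 1) for d in range(n_d)
        ),
        "GrayLevelNonUniformity": sum(m**2 for m in marg_g) / nz,
        "GrayLevelVariance": sum(
            p[g - 1, d] * (g - mu_g) ** 2 for g in range(1, n_g + 1) for d in range(n_d)
        ),
        "HighGrayLevelEmphasis": S(lambda g, j: g**2),
        "LargeDependenceEmphasis": S(lambda g, j: j**2),
        "LargeDependenceHighGrayLevelEmphasis": S(lambda g, j: g**2 * j**2),
        "LargeDependenceLowGrayLevelEmphasis": S(lambda g, j: j**2 / g**2),
        "LowGrayLevelEmphasis": S(lambda g, j: 1 / g**2),
        "SmallDependenceEmphasis": S(lambda g, j: 1 / j**2),
        "SmallDependenceHighGrayLevelEmphasis": S(lambda g, j: g**2 / j**2),
        "SmallDependenceLowGrayLevelEmphasis": S(lambda g, j: 1 / (g**2 * j**2)),
    }


# --------------------------------------------------------------- NGTDM ----

def bf_ngtdm_table(lev, ng):
    n = np.zeros(ng)
    s = np.zeros(ng)
    for v in _roi_voxels(lev):
        nbrs = []
        for off in OFFS_26:
            w = tuple(v[a] + off[a] for a in range(3))
            if _inside(lev.shape, w) and lev[w] > 0:
                nbrs.append(int(lev[w]))
        if not nbrs:
            continue
        g = int(lev[v])
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(nbrs) / len(nbrs))
    return n, s


def bf_ngtdm_features(lev, ng):
    n, s = bf_ngtdm_table(lev, ng)
    nv = n.sum()
    p = n / nv
    present = [i for i in range(1, ng + 1) if p[i - 1] > 0]
    ngp = len(present)
    ps = sum(p[i - 1] * s[i - 1] for i in present)
    coarseness = min(1.0 / ps, COARSENESS_CAP) if ps > 0 else COARSENESS_CAP
    if ngp > 1:
        contrast = (
            sum(p[i - 1] * p[j - 1] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * (s.sum() / nv)
        denom = sum(abs(i * p[i - 1] - j * p[j - 1]) for i in present for j in present)
        busyness = ps / denom if denom > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i - 1] * s[i - 1] + p[j - 1] * s[j - 1]) / (p[i - 1] + p[j - 1])
            for i in present for j in present
        ) / nv
        strength = (
            sum((p[i - 1] + p[j - 1]) * (i - j) ** 2 for i in present for j in present) / s.sum()
            if s.sum() > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ----------------------------------------------------------- first order ----

def bf_first_order(x, levels, ng, voxel_volume):
    x = sorted(float(v) for v in x)
    n = len(x)

    def pct(q):
        # linear interpolation between order statistics (numpy 'linear' rule)
        h = (n - 1) * q / 100.0
        lo = math.floor(h)
        hi = math.ceil(h)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    p10, p25, p75, p90 = pct(10), pct(25), pct(75), pct(90)
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    counts = {}
    for l in levels:
        counts[l] = counts.get(l, 0) + 1
    probs = [c / n for c in counts.values()]
    energy = sum(v**2 for v in x)
    return {
        "10Percentile": p10,
        "90Percentile": p90,
        "Energy": energy,
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "InterquartileRange": p75 - p25,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Maximum": x[-1],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "Mean": mean,
        "Median": pct(50),
        "Minimum": x[0],
        "Range": x[-1] - x[0],
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust) if robust else 0.0,
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "TotalEnergy": voxel_volume * energy,
        "Uniformity": sum(p**2 for p in probs),
        "Variance": m2,
    }
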