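"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — pure-Python loops, explicit
enumeration, dense optimizers — and shares no code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy import optimize


# ---------------------------------------------------------------------------
# Texture-matrix oracles (operate on a 3D integer level grid + boolean mask)
# ---------------------------------------------------------------------------

def naive_glcm(levels, mask, offset, G):
    """Symmetric normalized GLCM by enumerating every in-slice voxel pair."""
    dr, dc = offset
    nr, nc, ns = levels.shape
    P = np.zeros((G, G))
    for k in range(ns):
        for r in range(nr):
            for c in range(nc):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc and mask[r, c, k] and mask[r2, c2, k]:
                    a, b = levels[r, c, k] - 1, levels[r2, c2, k] - 1
                    P[a, b] += 1
                    P[b, a] += 1
    tot = P.sum()
    return P / tot if tot > 0 else P


def naive_glcm_features(P):
    G = P.shape[0]
    if P.sum() == 0:
        return {"glcm_energy": 0.0, "glcm_contrast": 0.0, "glcm_correlation": 1.0,
                "glcm_entropy": 0.0, "glcm_homogeneity": 0.0, "glcm_dissimilarity": 0.0,
                "glcm_sum_entropy": 0.0, "glcm_cluster_shade": 0.0,
                "glcm_cluster_prominence": 0.0}
    mu_x = sum((i + 1) * P[i, j] for i in range(G) for j in range(G))
    mu_y = sum((j + 1) * P[i, j] for i in range(G) for j in range(G))
    var_x = sum((i + 1 - mu_x) ** 2 * P[i, j] for i in range(G) for j in range(G))
    var_y = sum((j + 1 - mu_y) ** 2 * P[i, j] for i in range(G) for j in range(G))
    sx, sy = math.sqrt(var_x), math.sqrt(var_y)
    out = {"glcm_energy": 0.0, "glcm_contrast": 0.0, "glcm_entropy": 0.0,
           "glcm_homogeneity": 0.0, "glcm_dissimilarity": 0.0,
           "glcm_cluster_shade": 0.0, "glcm_cluster_prominence": 0.0}
    p_sum = {}
    corr_acc = 0.0
    for i in range(G):
        for j in range(G):
            p = P[i, j]
            if p == 0:
                continue
            d = (i + 1) - (j + 1)
            out["glcm_energy"] += p * p
            out["glcm_contrast"] += d * d * p
            out["glcm_entropy"] -= p * math.log2(p)
            out["glcm_homogeneity"] += p / (1 + d * d)
            out["glcm_dissimilarity"] += abs(d) * p
            dev = (i + 1) + (j + 1) - mu_x - mu_y
            out["glcm_cluster_shade"] += dev ** 3 * p
            out["glcm_cluster_prominence"] += dev ** 4 * p
            corr_acc += (i + 1) * (j + 1) * p
            p_sum[(i + 1) + (j + 1)] = p_sum.get((i + 1) + (j + 1), 0.0) + p
    out["glcm_correlation"] = ((corr_acc - mu_x * mu_y) / (sx * sy)) if sx > 0 and sy > 0 else 1.0
    out["glcm_sum_entropy"] = -sum(p * math.log2(p) for p in p_sum.values() if p > 0)
    return out


def naive_runs(levels, mask, direction):
    """All maximal same-level runs per axial slice as (level, length) pairs."""
    nr, nc, ns = levels.shape
    runs = []
    for k in range(ns):
        if direction == 0:
            lines = [[(r, c) for c in range(nc)] for r in range(nr)]
        elif direction == 90:
            lines = [[(r, c) for r in range(nr)] for c in range(nc)]
        elif direction == 45:  # step (+1, +1)
            starts = [(r, 0) for r in range(nr)] + [(0, c) for c in range(1, nc)]
            lines = []
            for r0, c0 in starts:
                line, r, c = [], r0, c0
                while r < nr and c < nc:
                    line.append((r, c))
                    r, c = r + 1, c + 1
                lines.append(line)
        else:  # 135: step (+1, -1)
            starts = [(0, c) for c in range(nc)] + [(r, nc - 1) for r in range(1, nr)]
            lines = []
            for r0, c0 in starts:
                line, r, c = [], r0, c0
                while r < nr and c >= 0:
                    line.append((r, c))
                    r, c = r + 1, c - 1
                lines.append(line)
        for line in lines:
            current, length = None, 0
            for (r, c) in line:
                v = levels[r, c, k] if mask[r, c, k] else None
                if v is not None and v == current:
                    length += 1
                else:
                    if current is not None:
                        runs.append((current, length))
                    current, length = v, (1 if v is not None else 0)
            if current is not None:
                runs.append((current, length))
    return runs


def naive_glrlm_features(runs, n_voxels):
    Nr = len(runs)
    if Nr == 0:
        return {k: 0.0 for k in (
            "glrlm_short_run_emphasis", "glrlm_long_run_emphasis",
            "glrlm_gray_level_nonuniformity", "glrlm_run_length_nonuniformity",
            "glrlm_run_percentage", "glrlm_low_gray_run_emphasis",
            "glrlm_high_gray_run_emphasis", "glrlm_short_run_low_gray_emphasis",
            "glrlm_short_run_high_gray_emphasis", "glrlm_long_run_low_gray_emphasis",
            "glrlm_long_run_high_gray_emphasis")}
    by_level, by_length = {}, {}
    for g, l in runs:
        by_level[g] = by_level.get(g, 0) + 1
        by_length[l] = by_length.get(l, 0) + 1
    return {
        "glrlm_short_run_emphasis": sum(1 / l ** 2 for _, l in runs) / Nr,
        "glrlm_long_run_emphasis": sum(l ** 2 for _, l in runs) / Nr,
        "glrlm_gray_level_nonuniformity": sum(v ** 2 for v in by_level.values()) / Nr,
        "glrlm_run_length_nonuniformity": sum(v ** 2 for v in by_length.values()) / Nr,
        "glrlm_run_percentage": Nr / n_voxels,
        "glrlm_low_gray_run_emphasis": sum(1 / g ** 2 for g, _ in runs) / Nr,
        "glrlm_high_gray_run_emphasis": sum(g ** 2 for g, _ in runs) / Nr,
        "glrlm_short_run_low_gray_emphasis": sum(1 / (g ** 2 * l ** 2) for g, l in runs) / Nr,
        "glrlm_short_run_high_gray_emphasis": sum(g ** 2 / l ** 2 for g, l in runs) / Nr,
        "glrlm_long_run_low_gray_emphasis": sum(l ** 2 / g ** 2 for g, l in runs) / Nr,
        "glrlm_long_run_high_gray_emphasis": sum(g ** 2 * l ** 2 for g, l in runs) / Nr,
    }


def naive_zones(levels, mask):
    """All 26-connected equal-level zones as (level, size) pairs (BFS flood fill)."""
    nr, nc, ns = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    nbrs = [(di, dj, dk) for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
            if (di, dj, dk) != (0, 0, 0)]
    for i in range(nr):
        for j in range(nc):
            for k in range(ns):
                if not mask[i, j, k] or seen[i, j, k]:
                    continue
                g = levels[i, j, k]
                size = 0
                queue = deque([(i, j, k)])
                seen[i, j, k] = True
                while queue:
                    a, b, c = queue.popleft()
                    size += 1
                    for di, dj, dk in nbrs:
                        x, y, z = a + di, b + dj, c + dk
                        if (0 <= x < nr and 0 <= y < nc and 0 <= z < ns
                                and mask[x, y, z] and not seen[x, y, z]
                                and levels[x, y, z] == g):
                            seen[x, y, z] = True
                            queue.append((x, y, z))
                zones.append((int(g), size))
    return zones


def naive_glzsm_features(zones):
    Nz = len(zones)
    if Nz == 0:
        return {k: 0.0 for k in (
            "glzsm_high_intensity_emphasis", "glzsm_high_intensity_large_area_emphasis",
            "glzsm_low_intensity_emphasis", "glzsm_low_intensity_large_area_emphasis")}
    return {
        "glzsm_high_intensity_emphasis": sum(g ** 2 for g, _ in zones) / Nz,
        "glzsm_high_intensity_large_area_emphasis": sum(g ** 2 * s ** 2 for g, s in zones) / Nz,
        "glzsm_low_intensity_emphasis": sum(1 / g ** 2 for g, _ in zones) / Nz,
        "glzsm_low_intensity_large_area_emphasis": sum(s ** 2 / g ** 2 for g, s in zones) / Nz,
    }


def naive_first_order(raw, levels_in_mask, G):
    x = [float(v) for v in raw]
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    if var > 0:
        m3 = sum((v - mu) ** 3 for v in x) / n
        m4 = sum((v - mu) ** 4 for v in x) / n
        skew, kurt = m3 / var ** 1.5, m4 / var ** 2 - 3.0
    else:
        skew = kurt = 0.0
    counts = {}
    for g in levels_in_mask:
        counts[int(g)] = counts.get(int(g), 0) + 1
    probs = [c / n for c in counts.values()]
    xs = sorted(x)
    median = (xs[n // 2] if n % 2 == 1 else (xs[n // 2 - 1] + xs[n // 2]) / 2)
    return {
        "mean": mu, "median": median, "minimum": min(x), "maximum": max(x),
        "range": max(x) - min(x), "variance": var, "skewness": skew, "kurtosis": kurt,
        "energy": sum(p * p for p in probs),
        "entropy": -sum(p * math.log2(p) for p in probs if p > 0),
        "uniformity": sum(p * p for p in probs),
        "mean_absolute_deviation": sum(abs(v - mu) for v in x) / n,
    }


# ---------------------------------------------------------------------------
# SVM dual QP oracle
# ---------------------------------------------------------------------------

def qp_dual_solve(K, y, C):
    """Dense soft-margin dual solve by SLSQP: min 1/2 b'Qb - sum(b)."""
    y = np.asarray(y, dtype=float)
    m = len(y)
    Q = (y[:, None] * y[None, :]) * K
    Q = Q + 1e-10 * np.eye(m)  # keep the Hessian numerically PSD

    def obj(b):
        return 0.5 * b @ Q @ b - b.sum()

    def grad(b):
        return Q @ b - np.ones(m)

    res = optimize.minimize(
        obj, x0=np.full(m, min(C, 1.0) / 2), jac=grad, method="SLSQP",
        bounds=[(0.0, C)] * m,
        constraints=[{"type": "eq", "fun": lambda b: b @ y, "jac": lambda b: y}],
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    return res.x


def qp_dual_objective(beta, y, K):
    by = beta * np.asarray(y, dtype=float)
    return float(beta.sum() - 0.5 * by @ K @ by)


# ---------------------------------------------------------------------------
# AUC oracle
# ---------------------------------------------------------------------------

def auc_concordant_pairs(scores, labels):
    """AUC as the tie-halved fraction of concordant (positive, negative) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l != 1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
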