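"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's vectorized code paths: the GLCM is
accumulated by explicit voxel iteration and every texture feature is
recomputed with plain double loops straight from its textbook definition.
"""

from __future__ import annotations

import math

import numpy as np

DIRECTIONS_13 = [
    d
    for d in (
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    )
    if d != (0, 0, 0) and d > tuple(-c for c in d)
]


def brute_glcm(levels: np.ndarray, mask: np.ndarray, direction, distance=1):
    """Pair-enumeration GLCM: returns Ng x Ng probabilities or None."""
    ng = int(levels[mask].max())
    counts = np.zeros((ng, ng))
    nx, ny, nz = levels.shape
    dx, dy, dz = (c * distance for c in direction)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                u, v, w = x + dx, y + dy, z + dz
                if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                    a, b = levels[x, y, z] - 1, levels[u, v, w] - 1
                    counts[a, b] += 1
                    counts[b, a] += 1
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def _log2(x: float) -> float:
    return math.log2(x) if x > 0 else 0.0


def brute_glcm_features(p: np.ndarray) -> dict[str, float]:
    """All 25 texture features by naive summation over matrix entries."""
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))

    p_sum: dict[int, float] = {}
    p_diff: dict[int, float] = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + p[i][j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p[i][j]

    out = {}
    out["glcm_autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)
    )
    for name, power in (
        ("glcm_cluster_prominence", 4),
        ("glcm_cluster_shade", 3),
        ("glcm_cluster_tendency", 2),
    ):
        out[name] = sum(
            (i + 1 + j + 1 - mu_x - mu_y) ** power * p[i][j]
            for i in range(ng)
            for j in range(ng)
        )
    out["glcm_contrast"] = sum(
        (i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
    )
    if sig_x > 0 and sig_y > 0:
        out["glcm_correlation"] = (
            out["glcm_autocorrelation"] - mu_x * mu_y
        ) / (sig_x * sig_y)
    else:
        out["glcm_correlation"] = 1.0
    da = sum(k * v for k, v in p_diff.items())
    out["glcm_difference_average"] = da
    out["glcm_difference_entropy"] = -sum(v * _log2(v) for v in p_diff.values())
    out["glcm_difference_variance"] = sum(
        (k - da) ** 2 * v for k, v in p_diff.items()
    )
    out["glcm_average_intensity"] = mu_x
    out["glcm_dissimilarity"] = sum(
        abs(i - j) * p[i][j] for i in range(ng) for j in range(ng)
    )
    out["glcm_energy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    hxy = -sum(p[i][j] * _log2(p[i][j]) for i in range(ng) for j in range(ng))
    out["glcm_entropy"] = hxy
    out["glcm_homogeneity1"] = sum(
        p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    out["glcm_homogeneity2"] = sum(
        p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    out["glcm_idmn"] = sum(
        p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
    )
    out["glcm_idn"] = sum(
        p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    out["glcm_inverse_variance"] = sum(
        p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    out["glcm_maximum_probability"] = max(
        p[i][j] for i in range(ng) for j in range(ng)
    )
    sa = sum(k * v for k, v in p_sum.items())
    se = -sum(v * _log2(v) for v in p_sum.values())
    out["glcm_sum_average"] = sa
    out["glcm_sum_entropy"] = se
    out["glcm_sum_variance"] = sum((k - se) ** 2 * v for k, v in p_sum.items())
    out["glcm_sum_of_squares"] = sum(
        (i + 1 - mu_x) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
    )
    hx = -sum(v * _log2(v) for v in px)
    hy = -sum(v * _log2(v) for v in py)
    hxy1 = -sum(
        p[i][j] * _log2(px[i] * py[j]) for i in range(ng) for j in range(ng)
    )
    hxy2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j]) for i in range(ng) for j in range(ng)
    )
    if hx == 0.0 and hy == 0.0:
        out["glcm_imc1"] = 0.0
        out["glcm_imc2"] = 0.0
    else:
        out["glcm_imc1"] = (hxy - hxy1) / max(hx, hy)
        out["glcm_imc2"] = math.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - hxy))))
    return out


def brute_direction_averaged_features(levels, mask, distance=1):
    feats = []
    for d in DIRECTIONS_13:
        p = brute_glcm(levels, mask, d, distance)
        if p is not None:
            feats.append(brute_glcm_features(p))
    names = feats[0].keys()
    return {n: float(np.mean([f[n] for f in feats])) for n in names}
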