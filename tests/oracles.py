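"""Independent brute-force oracles for the texture engine tests.

Everything here is written as plain nested loops over pixels and matrix
cells — deliberately naive, sharing no code with the package — so matrix
and feature computations can be checked against a second, independent
route.
"""

from __future__ import annotations

import math

import numpy as np

ANGLES = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def glcm_pairs(levels, mask, ng, distance=1):
    """Co-occurrence counts by explicit pixel-pair enumeration (symmetric)."""
    h, w = levels.shape
    out = np.zeros((4, ng, ng), dtype=np.int64)
    for a, (dr, dc) in enumerate(ANGLES):
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr * distance, c + dc * distance
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    i, j = levels[r, c] - 1, levels[r2, c2] - 1
                    out[a, i, j] += 1
                    out[a, j, i] += 1
    return out


def glrlm_runs(levels, mask, ng):
    """Maximal-run listing by walking every line in every direction."""
    h, w = levels.shape
    nr = max(h, w)
    out = np.zeros((4, ng, nr), dtype=np.int64)
    for d, (dr, dc) in enumerate(ANGLES):
        starts = []
        for r in range(h):
            for c in range(w):
                rp, cp = r - dr, c - dc
                if not (0 <= rp < h and 0 <= cp < w):
                    starts.append((r, c))
        for r0, c0 in starts:
            line = []
            r, c = r0, c0
            while 0 <= r < h and 0 <= c < w:
                line.append((r, c))
                r, c = r + dr, c + dc
            run_level, run_len = None, 0
            for r, c in line + [(-1, -1)]:
                lv = levels[r, c] if (r >= 0 and mask[r, c]) else None
                if lv == run_level and lv is not None:
                    run_len += 1
                else:
                    if run_level is not None:
                        out[d, run_level - 1, run_len - 1] += 1
                    run_level, run_len = lv, 1
    return out


def glszm_zones(levels, mask, ng):
    """Zone counts by explicit flood fill with 8-connectivity."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                lv = levels[r, c]
                stack = [(r, c)]
                seen[r, c] = True
                size = 0
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                                    and not seen[ny, nx] and levels[ny, nx] == lv):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                zones.append((lv, size))
    if not zones:
        return np.zeros((ng, 1), dtype=np.int64)
    max_size = max(s for _, s in zones)
    out = np.zeros((ng, max_size), dtype=np.int64)
    for lv, s in zones:
        out[lv - 1, s - 1] += 1
    return out


def gldm_dependences(levels, mask, ng, alpha=0):
    """Dependence counts by explicit neighbor counting per masked pixel."""
    h, w = levels.shape
    deps = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            d = 0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dy, dx) == (0, 0):
                        continue
                    ny, nx = r + dy, c + dx
                    if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                            and abs(int(levels[ny, nx]) - int(levels[r, c])) <= alpha):
                        d += 1
            deps.append((levels[r, c], d))
    nd = max(d for _, d in deps) + 1
    out = np.zeros((ng, nd), dtype=np.int64)
    for lv, d in deps:
        out[lv - 1, d] += 1
    return out


# --------------------------------------------------------------------------
# Direct-formula feature evaluation (loops over matrix cells)


def glcm_features_direct(counts_per_angle):
    """Angle-averaged GLCM features evaluated cell by cell."""
    per_angle = []
    for counts in counts_per_angle:
        total = counts.sum()
        if total == 0:
            continue
        ng = counts.shape[0]
        p = counts / total
        px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
        py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
        ux = sum((i + 1) * px[i] for i in range(ng))
        uy = sum((j + 1) * py[j] for j in range(ng))
        sx = math.sqrt(sum((i + 1 - ux) ** 2 * px[i] for i in range(ng)))
        sy = math.sqrt(sum((j + 1 - uy) ** 2 * py[j] for j in range(ng)))
        p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
        p_diff = {k: 0.0 for k in range(0, ng)}
        for i in range(ng):
            for j in range(ng):
                p_sum[i + j + 2] += p[i][j]
                p_diff[abs(i - j)] += p[i][j]
        def h(vals):
            return -sum(v * math.log2(v) for v in vals if v > 0)
        hxy = h(p[i][j] for i in range(ng) for j in range(ng))
        hx, hy = h(px), h(py)
        hxy1 = -sum(p[i][j] * math.log2(px[i] * py[j])
                    for i in range(ng) for j in range(ng)
                    if p[i][j] > 0 and px[i] * py[j] > 0)
        hxy2 = h(px[i] * py[j] for i in range(ng) for j in range(ng))
        f = {}
        f["Autocorrelation"] = sum(p[i][j] * (i + 1) * (j + 1)
                                   for i in range(ng) for j in range(ng))
        f["JointAverage"] = ux
        for name, power in (("ClusterTendency", 2), ("ClusterShade", 3),
                            ("ClusterProminence", 4)):
            f[name] = sum(p[i][j] * (i + 1 + j + 1 - ux - uy) ** power
                          for i in range(ng) for j in range(ng))
        f["Contrast"] = sum(p[i][j] * (i - j) ** 2
                            for i in range(ng) for j in range(ng))
        if sx > 0 and sy > 0:
            f["Correlation"] = sum(
                p[i][j] * (i + 1 - ux) * (j + 1 - uy)
                for i in range(ng) for j in range(ng)) / (sx * sy)
        else:
            f["Correlation"] = 1.0
        da = sum(k * v for k, v in p_diff.items())
        f["DifferenceAverage"] = da
        f["DifferenceEntropy"] = h(p_diff.values())
        f["DifferenceVariance"] = sum((k - da) ** 2 * v for k, v in p_diff.items())
        f["JointEnergy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
        f["JointEntropy"] = hxy
        f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
        if hxy2 >= hxy and hxy2 > 0:
            f["Imc2"] = math.sqrt(1 - math.exp(-2 * (hxy2 - hxy)))
        else:
            f["Imc2"] = 0.0
        f["Idm"] = sum(p[i][j] / (1 + (i - j) ** 2)
                       for i in range(ng) for j in range(ng))
        f["Idmn"] = sum(p[i][j] / (1 + ((i - j) / ng) ** 2)
                        for i in range(ng) for j in range(ng))
        f["Id"] = sum(p[i][j] / (1 + abs(i - j))
                      for i in range(ng) for j in range(ng))
        f["Idn"] = sum(p[i][j] / (1 + abs(i - j) / ng)
                       for i in range(ng) for j in range(ng))
        f["InverseVariance"] = sum(p[i][j] / (i - j) ** 2
                                   for i in range(ng) for j in range(ng) if i != j)
        f["MaximumProbability"] = max(p[i][j] for i in range(ng) for j in range(ng))
        f["SumAverage"] = sum(k * v for k, v in p_sum.items())
        f["SumEntropy"] = h(p_sum.values())
        f["SumSquares"] = sum(p[i][j] * (i + 1 - ux) ** 2
                              for i in range(ng) for j in range(ng))
        per_angle.append(f)
    return {k: sum(d[k] for d in per_angle) / len(per_angle) for k in per_angle[0]}


def glrlm_features_direct(counts_per_dir):
    per_dir = []
    for counts in counts_per_dir:
        total = counts.sum()
        if total == 0:
            continue
        ng, nr = counts.shape
        p = counts / total
        pg = [sum(p[i][j] for j in range(nr)) for i in range(ng)]
        pr = [sum(p[i][j] for i in range(ng)) for j in range(nr)]
        npix = sum(counts[i][j] * (j + 1) for i in range(ng) for j in range(nr))
        mu_g = sum(p[i][j] * (i + 1) for i in range(ng) for j in range(nr))
        mu_r = sum(p[i][j] * (j + 1) for i in range(ng) for j in range(nr))
        f = {
            "ShortRunEmphasis": sum(p[i][j] / (j + 1) ** 2
                                    for i in range(ng) for j in range(nr)),
            "LongRunEmphasis": sum(p[i][j] * (j + 1) ** 2
                                   for i in range(ng) for j in range(nr)),
            "GrayLevelNonUniformity": sum(g**2 for g in pg) * total,
            "GrayLevelNonUniformityNormalized": sum(g**2 for g in pg),
            "RunLengthNonUniformity": sum(r**2 for r in pr) * total,
            "RunLengthNonUniformityNormalized": sum(r**2 for r in pr),
            "RunPercentage": total / npix,
            "GrayLevelVariance": sum(p[i][j] * (i + 1 - mu_g) ** 2
                                     for i in range(ng) for j in range(nr)),
            "RunVariance": sum(p[i][j] * (j + 1 - mu_r) ** 2
                               for i in range(ng) for j in range(nr)),
            "RunEntropy": -sum(p[i][j] * math.log2(p[i][j])
                               for i in range(ng) for j in range(nr)
                               if p[i][j] > 0),
            "LowGrayLevelRunEmphasis": sum(p[i][j] / (i + 1) ** 2
                                           for i in range(ng) for j in range(nr)),
            "HighGrayLevelRunEmphasis": sum(p[i][j] * (i + 1) ** 2
                                            for i in range(ng) for j in range(nr)),
            "ShortRunLowGrayLevelEmphasis": sum(
                p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
                for i in range(ng) for j in range(nr)),
            "ShortRunHighGrayLevelEmphasis": sum(
                p[i][j] * (i + 1) ** 2 / (j + 1) ** 2
                for i in range(ng) for j in range(nr)),
            "LongRunLowGrayLevelEmphasis": sum(
                p[i][j] * (j + 1) ** 2 / (i + 1) ** 2
                for i in range(ng) for j in range(nr)),
            "LongRunHighGrayLevelEmphasis": sum(
                p[i][j] * (i + 1) ** 2 * (j + 1) ** 2
                for i in range(ng) for j in range(nr)),
        }
        per_dir.append(f)
    return {k: sum(d[k] for d in per_dir) / len(per_dir) for k in per_dir[0]}


def glszm_features_direct(counts, n_pixels):
    total = counts.sum()
    ng, ns = counts.shape
    p = counts / total
    pg = [sum(p[i][j] for j in range(ns)) for i in range(ng)]
    ps = [sum(p[i][j] for i in range(ng)) for j in range(ns)]
    mu_g = sum(p[i][j] * (i + 1) for i in range(ng) for j in range(ns))
    mu_s = sum(p[i][j] * (j + 1) for i in range(ng) for j in range(ns))
    return {
        "SmallAreaEmphasis": sum(p[i][j] / (j + 1) ** 2
                                 for i in range(ng) for j in range(ns)),
        "LargeAreaEmphasis": sum(p[i][j] * (j + 1) ** 2
                                 for i in range(ng) for j in range(ns)),
        "GrayLevelNonUniformity": sum(g**2 for g in pg) * total,
        "GrayLevelNonUniformityNormalized": sum(g**2 for g in pg),
        "SizeZoneNonUniformity": sum(s**2 for s in ps) * total,
        "SizeZoneNonUniformityNormalized": sum(s**2 for s in ps),
        "ZonePercentage": total / n_pixels,
        "GrayLevelVariance": sum(p[i][j] * (i + 1 - mu_g) ** 2
                                 for i in range(ng) for j in range(ns)),
        "ZoneVariance": sum(p[i][j] * (j + 1 - mu_s) ** 2
                            for i in range(ng) for j in range(ns)),
        "ZoneEntropy": -sum(p[i][j] * math.log2(p[i][j])
                            for i in range(ng) for j in range(ns) if p[i][j] > 0),
        "LowGrayLevelZoneEmphasis": sum(p[i][j] / (i + 1) ** 2
                                        for i in range(ng) for j in range(ns)),
        "HighGrayLevelZoneEmphasis": sum(p[i][j] * (i + 1) ** 2
                                         for i in range(ng) for j in range(ns)),
        "SmallAreaLowGrayLevelEmphasis": sum(
            p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
            for i in range(ng) for j in range(ns)),
        "SmallAreaHighGrayLevelEmphasis": sum(
            p[i][j] * (i + 1) ** 2 / (j + 1) ** 2
            for i in range(ng) for j in range(ns)),
        "LargeAreaLowGrayLevelEmphasis": sum(
            p[i][j] * (j + 1) ** 2 / (i + 1) ** 2
            for i in range(ng) for j in range(ns)),
        "LargeAreaHighGrayLevelEmphasis": sum(
            p[i][j] * (i + 1) ** 2 * (j + 1) ** 2
            for i in range(ng) for j in range(ns)),
    }


def gldm_features_direct(counts):
    total = counts.sum()
    ng, nd = counts.shape
    p = counts / total
    pg = [sum(p[i][j] for j in range(nd)) for i in range(ng)]
    pd = [sum(p[i][j] for i in range(ng)) for j in range(nd)]
    mu_g = sum(p[i][j] * (i + 1) for i in range(ng) for j in range(nd))
    mu_d = sum(p[i][j] * (j + 1) for i in range(ng) for j in range(nd))
    return {
        "SmallDependenceEmphasis": sum(p[i][j] / (j + 1) ** 2
                                       for i in range(ng) for j in range(nd)),
        "LargeDependenceEmphasis": sum(p[i][j] * (j + 1) ** 2
                                       for i in range(ng) for j in range(nd)),
        "GrayLevelNonUniformity": sum(g**2 for g in pg) * total,
        "DependenceNonUniformity": sum(d**2 for d in pd) * total,
        "DependenceNonUniformityNormalized": sum(d**2 for d in pd),
        "GrayLevelVariance": sum(p[i][j] * (i + 1 - mu_g) ** 2
                                 for i in range(ng) for j in range(nd)),
        "DependenceVariance": sum(p[i][j] * (j + 1 - mu_d) ** 2
                                  for i in range(ng) for j in range(nd)),
        "DependenceEntropy": -sum(p[i][j] * math.log2(p[i][j])
                                  for i in range(ng) for j in range(nd)
                                  if p[i][j] > 0),
        "LowGrayLevelEmphasis": sum(p[i][j] / (i + 1) ** 2
                                    for i in range(ng) for j in range(nd)),
        "HighGrayLevelEmphasis": sum(p[i][j] * (i + 1) ** 2
                                     for i in range(ng) for j in range(nd)),
        "SmallDependenceLowGrayLevelEmphasis": sum(
            p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
            for i in range(ng) for j in range(nd)),
        "SmallDependenceHighGrayLevelEmphasis": sum(
            p[i][j] * (i + 1) ** 2 / (j + 1) ** 2
            for i in range(ng) for j in range(nd)),
        "LargeDependenceLowGrayLevelEmphasis": sum(
            p[i][j] * (j + 1) ** 2 / (i + 1) ** 2
            for i in range(ng) for j in range(nd)),
        "LargeDependenceHighGrayLevelEmphasis": sum(
            p[i][j] * (i + 1) ** 2 * (j + 1) ** 2
            for i in range(ng) for j in range(nd)),
    }


def auc_pairwise(scores, labels):
    """AUC by exhaustive (positive, negative) pair comparison."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_quantized(rng, shape=(16, 16), ng=8, mask_density=0.7,
                     min_pixels=20):
    """Random level map + mask for oracle comparisons."""
    levels = rng.integers(1, ng + 1, size=shape)
    while True:
        mask = rng.random(shape) < mask_density
        if mask.sum() >= min_pixels:
            break
    levels = np.where(mask, levels, 0)
    return levels.astype(np.int32), mask
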