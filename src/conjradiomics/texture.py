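"""Texture count matrices and radiomic features from a quantized ROI.

Implements the four 2-D gray-level texture matrix families — co-occurrence
(GLCM), run length (GLRLM), size zone (GLSZM) and dependence (GLDM) — plus
first-order intensity statistics, following the standard radiomics feature
definitions. Matrices are built from masked pixels only; features are
computed per direction where a direction exists and averaged.

Feature names follow the ``filter|family|feature`` convention, e.g.
``Wavelet-H|GLDM|GrayLevelNonUniformity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from conjradiomics.image_prep import (
    QuantizedRoi,
    apply_log_filter,
    quantize_gray_levels,
    standardize_intensity,
    wavelet_subbands,
)

__all__ = [
    "GLCM",
    "GLRLM",
    "GLSZM",
    "GLDM",
    "ExtractionConfig",
    "compute_glcm",
    "compute_glrlm",
    "compute_glszm",
    "compute_gldm",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "first_order_features",
    "extract_feature_vector",
]

_EPS = np.finfo(float).tiny

# Direction vectors for GLCM / GLRLM: 0, 45, 90, 135 degrees.
_ANGLES = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class GLCM:
    """Gray level co-occurrence counts, one Ng x Ng matrix per angle.

    Accumulation is symmetric (each in-mask pixel pair counted in both
    orders), so every matrix equals its transpose.
    """

    counts: np.ndarray  # (n_angles, Ng, Ng) integer counts
    offsets: tuple = _ANGLES
    distance: int = 1


@dataclass
class GLRLM:
    """Gray level run length counts, one Ng x Nr matrix per direction."""

    counts: np.ndarray  # (n_dirs, Ng, Nr)
    directions: tuple = _ANGLES


@dataclass
class GLSZM:
    """Gray level size zone counts (orientation-free), Ng x Ns."""

    counts: np.ndarray
    n_pixels: int = 0


@dataclass
class GLDM:
    """Gray level dependence counts, Ng x (max dependence + 1)."""

    counts: np.ndarray
    alpha: int = 0


def _check_nonempty(q: QuantizedRoi) -> None:
    if not q.mask.any():
        raise ValueError("empty mask")


def compute_glcm(q: QuantizedRoi, distance: int = 1) -> GLCM:
    """Co-occurrence counts of level pairs at the given pixel distance.

    For each of the four unique 2-D angles, counts pairs of masked pixels
    separated by ``distance`` times the angle vector; symmetric
    accumulation counts each pair in both orders.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    _check_nonempty(q)
    ng = q.ng
    lv = q.levels
    mk = q.mask
    out = np.zeros((len(_ANGLES), ng, ng), dtype=np.int64)
    for a, (dr, dc) in enumerate(_ANGLES):
        dr, dc = dr * distance, dc * distance
        r0 = max(0, -dr)
        r1 = lv.shape[0] - max(0, dr)
        c0 = max(0, -dc)
        c1 = lv.shape[1] - max(0, dc)
        src_l = lv[r0:r1, c0:c1]
        dst_l = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mk[r0:r1, c0:c1] & mk[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        i = src_l[valid] - 1
        j = dst_l[valid] - 1
        m = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng)
        out[a] = m + m.T
    return GLCM(counts=out, distance=distance)


def _iter_lines(arr: np.ndarray, direction: tuple[int, int]):
    """Yield 1-D views of ``arr`` along the given direction."""
    dr, dc = direction
    if (dr, dc) == (0, 1):
        yield from arr
    elif (dr, dc) == (-1, 0):
        yield from arr.T
    elif (dr, dc) == (-1, 1):  # anti-diagonals
        fl = np.flipud(arr)
        for k in range(-fl.shape[0] + 1, fl.shape[1]):
            yield np.diagonal(fl, offset=k)
    elif (dr, dc) == (-1, -1):  # main diagonals
        fl = np.flipud(np.fliplr(arr))
        for k in range(-fl.shape[0] + 1, fl.shape[1]):
            yield np.diagonal(fl, offset=k)
    else:  # pragma: no cover - internal
        raise ValueError(f"unsupported direction {direction}")


def _sheared_diagonals(arr: np.ndarray) -> np.ndarray:
    """Flatten all anti-diagonals of ``arr`` with 0 separators between them.

    Rows are sheared into a zero-padded canvas whose columns are the
    anti-diagonals; a spare zero row guarantees a separator between
    consecutive columns after raveling. Zeros already mean "out of mask".
    """
    h, w = arr.shape
    z = np.zeros((h + 1, w + h), dtype=arr.dtype)
    for r in range(h):
        z[r, r : r + w] = arr[r]
    return z.T.ravel()


def _concat_lines(arr: np.ndarray, direction: tuple[int, int]) -> np.ndarray:
    """All lines of ``arr`` along ``direction`` joined with 0 separators."""
    h, w = arr.shape
    if direction == (0, 1):
        return np.hstack([arr, np.zeros((h, 1), dtype=arr.dtype)]).ravel()
    if direction == (-1, 0):
        return np.hstack([arr.T, np.zeros((w, 1), dtype=arr.dtype)]).ravel()
    if direction == (-1, 1):
        return _sheared_diagonals(arr)  # anti-diagonals: row+col constant
    if direction == (-1, -1):
        return _sheared_diagonals(np.fliplr(arr))  # main diagonals
    raise ValueError(f"unsupported direction {direction}")


def compute_glrlm(q: QuantizedRoi) -> GLRLM:
    """Counts of maximal runs of equal level, per direction, masked only.

    Runs break at mask boundaries (out-of-mask pixels act as separators).
    """
    _check_nonempty(q)
    ng = q.ng
    nr = max(q.levels.shape)
    masked = np.where(q.mask, q.levels, 0).astype(np.int64)
    out = np.zeros((len(_ANGLES), ng, nr), dtype=np.int64)
    for d, direction in enumerate(_ANGLES):
        v = _concat_lines(masked, direction)
        change = np.r_[0, np.nonzero(np.diff(v))[0] + 1]
        run_vals = v[change]
        run_lens = np.r_[np.diff(change), v.size - change[-1]]
        keep = run_vals > 0
        lv = run_vals[keep] - 1
        ln = run_lens[keep] - 1
        out[d] += np.bincount(lv * nr + ln, minlength=ng * nr).reshape(ng, nr)
    return GLRLM(counts=out)


def compute_glszm(q: QuantizedRoi) -> GLSZM:
    """Counts of 8-connected zones of equal level, by level and zone size."""
    _check_nonempty(q)
    ng = q.ng
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    zones: list[tuple[int, int]] = []
    max_size = 1
    masked = np.where(q.mask, q.levels, 0)
    present = np.unique(masked[q.mask])
    for level in present:
        binary = masked == level
        labeled, n = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            zones.append((level, int(s)))
            max_size = max(max_size, int(s))
    counts = np.zeros((ng, max_size), dtype=np.int64)
    for level, s in zones:
        counts[level - 1, s - 1] += 1
    return GLSZM(counts=counts, n_pixels=q.n_pixels)


def compute_gldm(q: QuantizedRoi, alpha: int = 0) -> GLDM:
    """Dependence counts: for each masked pixel, the number of masked
    8-neighbors whose level differs by at most ``alpha``."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    _check_nonempty(q)
    ng = q.ng
    lv = q.levels.astype(np.int64)
    mk = q.mask
    dep = np.zeros(lv.shape, dtype=np.int64)
    shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    for dr, dc in shifts:
        r0 = max(0, -dr)
        r1 = lv.shape[0] - max(0, dr)
        c0 = max(0, -dc)
        c1 = lv.shape[1] - max(0, dc)
        src = lv[r0:r1, c0:c1]
        nb = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (
            mk[r0:r1, c0:c1]
            & mk[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
            & (np.abs(src - nb) <= alpha)
        )
        dep[r0:r1, c0:c1] += ok
    nd = int(dep[mk].max()) + 1
    counts = np.zeros((ng, nd), dtype=np.int64)
    np.add.at(counts, (lv[mk] - 1, dep[mk]), 1)
    return GLDM(counts=counts, alpha=alpha)


# --------------------------------------------------------------------------
# Feature computation


def _xlogx(v: np.ndarray) -> np.ndarray:
    """v * log2(v) with the 0 log 0 = 0 convention."""
    return np.where(v > 0, v * np.log2(np.maximum(v, _EPS)), 0.0)


def glcm_features(m: GLCM) -> dict[str, float]:
    """Angle-averaged standard GLCM features (normalized per angle).

    Degenerate conventions: a single occupied cell gives Correlation = 1
    (a level is perfectly correlated with itself) and Imc2 = 0 (the joint
    entropy equals the marginal-product entropy).
    """
    totals = m.counts.sum(axis=(1, 2))
    keep = totals > 0
    if not keep.any():
        raise ValueError("all angle matrices are empty")
    P = m.counts[keep].astype(float) / totals[keep][:, None, None]
    a, ng = P.shape[0], P.shape[1]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=2)  # (a, ng) row marginal
    py = P.sum(axis=1)
    ux = (px * i).sum(axis=1)
    uy = (py * i).sum(axis=1)
    sx = np.sqrt((((i - ux[:, None]) ** 2) * px).sum(axis=1))
    sy = np.sqrt((((i - uy[:, None]) ** 2) * py).sum(axis=1))

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    k_diff = np.arange(0, ng, dtype=float)
    sum_idx = (ii + jj).astype(int).ravel() - 2
    diff_idx = np.abs(ii - jj).astype(int).ravel()
    p_sum = np.stack(
        [np.bincount(sum_idx, weights=P[x].ravel(), minlength=2 * ng - 1)
         for x in range(a)])
    p_diff = np.stack(
        [np.bincount(diff_idx, weights=P[x].ravel(), minlength=ng)
         for x in range(a)])

    hxy = -_xlogx(P).sum(axis=(1, 2))
    hx = -_xlogx(px).sum(axis=1)
    hy = -_xlogx(py).sum(axis=1)
    pxy = px[:, :, None] * py[:, None, :]
    log_pxy = np.log2(np.maximum(pxy, _EPS))
    hxy1 = -(np.where(P > 0, P * log_pxy, 0.0)).sum(axis=(1, 2))
    hxy2 = -(np.where(pxy > 0, pxy * log_pxy, 0.0)).sum(axis=(1, 2))

    dev = ii[None] + jj[None] - (ux + uy)[:, None, None]
    diff2 = (ii - jj) ** 2
    corr_num = (P * (ii[None] - ux[:, None, None])
                * (jj[None] - uy[:, None, None])).sum(axis=(1, 2))
    sxsy = sx * sy
    correlation = np.where(sxsy > 0, corr_num / np.where(sxsy > 0, sxsy, 1.0), 1.0)
    da = (k_diff * p_diff).sum(axis=1)
    div = np.maximum(hx, hy)
    imc1 = np.where(div > 0, (hxy - hxy1) / np.where(div > 0, div, 1.0), 0.0)
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = np.where((hxy2 >= hxy) & (hxy2 > 0), np.sqrt(np.maximum(imc2_arg, 0.0)), 0.0)
    inv_w = np.zeros_like(diff2)
    off = diff2 > 0
    inv_w[off] = 1.0 / diff2[off]

    per_angle = {
        "Autocorrelation": (P * (ii * jj)[None]).sum(axis=(1, 2)),
        "JointAverage": ux,
        "ClusterProminence": (P * dev**4).sum(axis=(1, 2)),
        "ClusterShade": (P * dev**3).sum(axis=(1, 2)),
        "ClusterTendency": (P * dev**2).sum(axis=(1, 2)),
        "Contrast": (P * diff2[None]).sum(axis=(1, 2)),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": -_xlogx(p_diff).sum(axis=1),
        "DifferenceVariance": (((k_diff - da[:, None]) ** 2) * p_diff).sum(axis=1),
        "JointEnergy": (P**2).sum(axis=(1, 2)),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": (P / (1 + diff2)[None]).sum(axis=(1, 2)),
        "Idmn": (P / (1 + diff2 / ng**2)[None]).sum(axis=(1, 2)),
        "Id": (P / (1 + np.abs(ii - jj))[None]).sum(axis=(1, 2)),
        "Idn": (P / (1 + np.abs(ii - jj) / ng)[None]).sum(axis=(1, 2)),
        "InverseVariance": (P * inv_w[None]).sum(axis=(1, 2)),
        "MaximumProbability": P.max(axis=(1, 2)),
        "SumAverage": (k_sum * p_sum).sum(axis=1),
        "SumEntropy": -_xlogx(p_sum).sum(axis=1),
        "SumSquares": (P * ((ii - ux[:, None, None]) ** 2)).sum(axis=(1, 2)),
    }
    return {k: float(np.mean(v)) for k, v in per_angle.items()}


def glrlm_features(m: GLRLM) -> dict[str, float]:
    """Direction-averaged standard GLRLM features."""
    totals = m.counts.sum(axis=(1, 2))
    keep = totals > 0
    if not keep.any():
        raise ValueError("all direction matrices are empty")
    counts = m.counts[keep].astype(float)
    # trim the run-length axis to the longest observed run
    nl_eff = int(np.max(np.nonzero(counts.sum(axis=(0, 1)))[0])) + 1
    counts = counts[:, :, :nl_eff]
    nr_total = totals[keep].astype(float)
    P = counts / nr_total[:, None, None]
    ng = counts.shape[1]
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nl_eff + 1, dtype=float)[None, :]
    pg = P.sum(axis=2)
    pr = P.sum(axis=1)
    np_pixels = (counts * j[None]).sum(axis=(1, 2))
    mu_g = (P * i[None]).sum(axis=(1, 2))
    mu_r = (P * j[None]).sum(axis=(1, 2))
    per_dir = {
        "ShortRunEmphasis": (P / (j**2)[None]).sum(axis=(1, 2)),
        "LongRunEmphasis": (P * (j**2)[None]).sum(axis=(1, 2)),
        "GrayLevelNonUniformity": (pg**2).sum(axis=1) * nr_total,
        "GrayLevelNonUniformityNormalized": (pg**2).sum(axis=1),
        "RunLengthNonUniformity": (pr**2).sum(axis=1) * nr_total,
        "RunLengthNonUniformityNormalized": (pr**2).sum(axis=1),
        "RunPercentage": nr_total / np_pixels,
        "GrayLevelVariance": (P * (i[None] - mu_g[:, None, None]) ** 2).sum(axis=(1, 2)),
        "RunVariance": (P * (j[None] - mu_r[:, None, None]) ** 2).sum(axis=(1, 2)),
        "RunEntropy": -_xlogx(P).sum(axis=(1, 2)),
        "LowGrayLevelRunEmphasis": (P / (i**2)[None]).sum(axis=(1, 2)),
        "HighGrayLevelRunEmphasis": (P * (i**2)[None]).sum(axis=(1, 2)),
        "ShortRunLowGrayLevelEmphasis": (P / (i**2 * j**2)[None]).sum(axis=(1, 2)),
        "ShortRunHighGrayLevelEmphasis": (P * (i**2 / j**2)[None]).sum(axis=(1, 2)),
        "LongRunLowGrayLevelEmphasis": (P * (j**2 / i**2)[None]).sum(axis=(1, 2)),
        "LongRunHighGrayLevelEmphasis": (P * (i**2 * j**2)[None]).sum(axis=(1, 2)),
    }
    return {k: float(np.mean(v)) for k, v in per_dir.items()}


def _sz_like_features(counts: np.ndarray, n_pixels: int, prefix_small: str,
                      prefix_large: str, size_name: str) -> dict[str, float]:
    """Shared SZM-style feature formulas over a (level, size) count matrix."""
    nz = counts.sum()
    p = counts / nz
    ng, ns = counts.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, ns + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    f: dict[str, float] = {}
    f[f"Small{prefix_small}Emphasis"] = float((p / j**2).sum())
    f[f"Large{prefix_large}Emphasis"] = float((p * j**2).sum())
    f["GrayLevelNonUniformity"] = float((pg**2).sum() * nz)
    f["GrayLevelNonUniformityNormalized"] = float((pg**2).sum())
    f[f"{size_name}NonUniformity"] = float((ps**2).sum() * nz)
    f[f"{size_name}NonUniformityNormalized"] = float((ps**2).sum())
    f["ZonePercentage"] = float(nz / n_pixels)
    mu_g = float((p * i).sum())
    f["GrayLevelVariance"] = float((p * (i - mu_g) ** 2).sum())
    mu_s = float((p * j).sum())
    f["ZoneVariance"] = float((p * (j - mu_s) ** 2).sum())
    f["ZoneEntropy"] = float(-(p * np.log2(p + _EPS))[p > 0].sum())
    f["LowGrayLevelZoneEmphasis"] = float((p / i**2).sum())
    f["HighGrayLevelZoneEmphasis"] = float((p * i**2).sum())
    f[f"Small{prefix_small}LowGrayLevelEmphasis"] = float((p / (i**2 * j**2)).sum())
    f[f"Small{prefix_small}HighGrayLevelEmphasis"] = float((p * i**2 / j**2).sum())
    f[f"Large{prefix_large}LowGrayLevelEmphasis"] = float((p * j**2 / i**2).sum())
    f[f"Large{prefix_large}HighGrayLevelEmphasis"] = float((p * i**2 * j**2).sum())
    return f


def glszm_features(m: GLSZM) -> dict[str, float]:
    """Standard GLSZM features (single orientation-free matrix)."""
    if m.counts.sum() == 0:
        raise ValueError("empty size zone matrix")
    return _sz_like_features(m.counts, m.n_pixels, "Area", "Area", "SizeZone")


def gldm_features(m: GLDM) -> dict[str, float]:
    """Standard GLDM features over the (level, dependence) count matrix.

    Dependence counts of zero are valid (isolated masked pixels), so the
    size axis here is dependence+1 to keep the 1-based formula weights.
    """
    counts = m.counts
    nz = counts.sum()
    if nz == 0:
        raise ValueError("empty dependence matrix")
    p = counts / nz
    ng, nd = counts.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nd + 1, dtype=float)[None, :]  # dependence + 1
    pg = p.sum(axis=1)
    pd_ = p.sum(axis=0)
    f: dict[str, float] = {}
    f["SmallDependenceEmphasis"] = float((p / j**2).sum())
    f["LargeDependenceEmphasis"] = float((p * j**2).sum())
    f["GrayLevelNonUniformity"] = float((pg**2).sum() * nz)
    f["DependenceNonUniformity"] = float((pd_**2).sum() * nz)
    f["DependenceNonUniformityNormalized"] = float((pd_**2).sum())
    mu_g = float((p * i).sum())
    f["GrayLevelVariance"] = float((p * (i - mu_g) ** 2).sum())
    mu_d = float((p * j).sum())
    f["DependenceVariance"] = float((p * (j - mu_d) ** 2).sum())
    f["DependenceEntropy"] = float(-(p * np.log2(p + _EPS))[p > 0].sum())
    f["LowGrayLevelEmphasis"] = float((p / i**2).sum())
    f["HighGrayLevelEmphasis"] = float((p * i**2).sum())
    f["SmallDependenceLowGrayLevelEmphasis"] = float((p / (i**2 * j**2)).sum())
    f["SmallDependenceHighGrayLevelEmphasis"] = float((p * i**2 / j**2).sum())
    f["LargeDependenceLowGrayLevelEmphasis"] = float((p * j**2 / i**2).sum())
    f["LargeDependenceHighGrayLevelEmphasis"] = float((p * i**2 * j**2).sum())
    return f


def first_order_features(gray, mask, n_bins: int = 32) -> dict[str, float]:
    """First-order statistics of the in-mask intensity distribution.

    Entropy and uniformity use an ``n_bins`` equal-width histogram over the
    within-ROI range (a constant ROI occupies one bin: entropy 0,
    uniformity 1). Percentiles use linear interpolation. Skewness and
    kurtosis (Fisher, i.e. excess) are 0 by convention on zero variance.
    """
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = gray[mask]
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    f: dict[str, float] = {
        "Mean": mean,
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": var,
        "Energy": float((x**2).sum()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "InterquartileRange": float(p75 - p25),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
    }
    if var > 0:
        sd = np.sqrt(var)
        f["Skewness"] = float(((x - mean) ** 3).mean() / sd**3)
        f["Kurtosis"] = float(((x - mean) ** 4).mean() / sd**4 - 3.0)
    else:
        f["Skewness"] = 0.0
        f["Kurtosis"] = 0.0
    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    else:
        hist = np.array([n])
    p = hist[hist > 0] / n
    f["Entropy"] = float(-(p * np.log2(p)).sum())
    f["Uniformity"] = float((p**2).sum())
    return f


@dataclass
class ExtractionConfig:
    """Which filtered images and matrix settings to extract features from.

    ``log_sigmas`` are LoG scales in pixels; ``wavelet_subbands`` selects
    from L (LL), H (HH), LH, HL; ``ng`` is the gray-level count used for
    discretization; GLCM distance and GLDM alpha follow the standard
    defaults (1 and 0).
    """

    include_original: bool = True
    log_sigmas: tuple[float, ...] = (1.0, 2.0, 3.0)
    wavelet_subbands: tuple[str, ...] = ("L", "H")
    wavelet_kernel: str = "haar"
    ng: int = 32
    glcm_distance: int = 1
    gldm_alpha: int = 0
    grayscale_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def image_types(self) -> list[str]:
        names = []
        if self.include_original:
            names.append("Original")
        names += [f"LoG-sigma-{g:g}" for g in self.log_sigmas]
        names += [f"Wavelet-{b}" for b in self.wavelet_subbands]
        return names


def _feature_families(gray: np.ndarray, mask: np.ndarray,
                      config: ExtractionConfig) -> dict[str, float]:
    """First-order + all four matrix families on one (filtered) image.

    Inputs are cropped to the mask bounding box first; all features depend
    only on in-mask pixels, so this is exact.
    """
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    if rows.size:
        sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
        gray, mask = gray[sl], mask[sl]
    out: dict[str, float] = {}
    for name, val in first_order_features(gray, mask, n_bins=config.ng).items():
        out[f"FirstOrder|{name}"] = val
    q = quantize_gray_levels(gray, mask, config.ng)
    for name, val in glcm_features(compute_glcm(q, config.glcm_distance)).items():
        out[f"GLCM|{name}"] = val
    for name, val in glrlm_features(compute_glrlm(q)).items():
        out[f"GLRLM|{name}"] = val
    for name, val in glszm_features(compute_glszm(q)).items():
        out[f"GLSZM|{name}"] = val
    for name, val in gldm_features(compute_gldm(q, config.gldm_alpha)).items():
        out[f"GLDM|{name}"] = val
    return out


def extract_feature_vector(photo, config: ExtractionConfig | None = None,
                           errors: list | None = None) -> dict[str, float]:
    """Full radiomic feature vector for one photo (image + aligned mask).

    For each enabled image type (original, LoG per sigma, wavelet subbands)
    the intensity is standardized within the ROI and the first-order plus
    GLCM/GLRLM/GLSZM/GLDM features are computed. Shape features are never
    computed. A family failure records NaN for its features (propagating to
    imputation) and appends the cause to ``errors`` if provided.

    ``photo`` is any object with ``image`` and ``mask`` attributes (e.g. a
    :class:`~conjradiomics.phantom.PhotoRecord`), or a ``(image, mask)``
    pair.
    """
    if config is None:
        config = ExtractionConfig()
    if hasattr(photo, "image"):
        image, mask = photo.image, photo.mask
    else:
        image, mask = photo
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask must align with the image")
    if image.ndim == 3:
        from conjradiomics.image_prep import to_grayscale

        image = to_grayscale(image, config.grayscale_weights)

    variants: dict[str, np.ndarray] = {}
    base = standardize_intensity(image, mask)
    if config.include_original:
        variants["Original"] = base
    for g in config.log_sigmas:
        variants[f"LoG-sigma-{g:g}"] = apply_log_filter(image, g, mask=mask)
    if config.wavelet_subbands:
        bands = wavelet_subbands(
            image, mask=mask, wavelet=config.wavelet_kernel,
            subbands=config.wavelet_subbands,
        )
        for b, img in bands.items():
            variants[f"Wavelet-{b}"] = img

    features: dict[str, float] = {}
    for name, img in variants.items():
        try:
            fam = _feature_families(img, mask, config)
        except Exception as exc:  # degenerate ROI under this filter
            if errors is not None:
                errors.append(f"{name}: {exc}")
            fam = {}
        for key, val in fam.items():
            features[f"{name}|{key}"] = val
    return features
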