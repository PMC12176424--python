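"""Image preparation: grayscale conversion, ROI intensity standardization,
filtered-image generation (LoG, undecimated wavelet subbands), gray-level
discretization, and the edge-method spatial-resolution estimator.

All filters operate on the full frame (mirror boundary handling) before any
masking, so filtered-image features may legitimately depend on pixels within
the filter support of the ROI boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

__all__ = [
    "QuantizedRoi",
    "to_grayscale",
    "standardize_intensity",
    "apply_log_filter",
    "wavelet_subbands",
    "quantize_gray_levels",
    "estimate_resolution_fwhm",
]

#: ITU-R BT.601 luma weights, offered as an alternative to the balanced
#: (equal-weight) default.
BT601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class QuantizedRoi:
    """ROI pixels discretized to integer gray levels 1..Ng.

    ``levels`` is 0 outside the mask (sentinel); every masked pixel carries
    exactly one level. ``bin_edges`` are the Ng+1 intensity thresholds of
    the equal-width binning over the within-ROI [min, max] range.
    """

    levels: np.ndarray  # int array, 0 = outside mask
    mask: np.ndarray  # bool array, same shape
    ng: int
    bin_edges: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def to_grayscale(rgb_image, weights=(1 / 3, 1 / 3, 1 / 3)) -> np.ndarray:
    """Collapse a 3-channel image to one intensity channel.

    The default is the balanced combination (equal channel weights); pass
    :data:`BT601_WEIGHTS` for the ITU-R BT.601 luma instead. Weights are
    normalized to sum to 1, so a gray input pixel is a fixed point.
    """
    arr = np.asarray(rgb_image, dtype=float)
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {arr.shape}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or w.sum() <= 0:
        raise ValueError("weights must be 3 non-negative values with positive sum")
    w = w / w.sum()
    return arr @ w


def standardize_intensity(gray, mask) -> np.ndarray:
    """Affinely map within-ROI intensities so ROI min -> 0 and ROI max -> 255.

    The mapping fitted on the ROI is applied to the full frame (so filters
    applied afterwards see consistent values near the boundary). A constant
    ROI maps to 128 everywhere. Idempotent on already-standardized input.
    """
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gray.shape:
        raise ValueError("mask shape must equal image shape")
    if not mask.any():
        raise ValueError("empty mask")
    vals = gray[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return np.full_like(gray, 128.0)
    # ratio first: the ROI max maps to exactly 255.0
    return (gray - lo) / (hi - lo) * 255.0


def apply_log_filter(gray, sigma: float, mask=None) -> np.ndarray:
    """Laplacian-of-Gaussian band-pass filter at scale ``sigma`` (pixels).

    Filtering covers the full frame with mirror padding. If ``mask`` is
    given, the response is re-standardized to [0, 255] within the ROI
    (the form consumed by feature extraction); with ``mask=None`` the raw
    response is returned.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    gray = np.asarray(gray, dtype=float)
    resp = ndimage.convolve(gray, _log_kernel(sigma), mode="mirror")
    if mask is None:
        return resp
    return standardize_intensity(resp, mask)


def _log_kernel(sigma: float) -> np.ndarray:
    """Zero-sum Laplacian-of-Gaussian kernel (truncated at 4 sigma).

    The truncated analytic kernel has a small positive sum, which would
    leak a DC response; subtracting the mean restores an exactly zero
    response to constant (and, by symmetry, affine) images.
    """
    r = max(int(np.ceil(4.0 * sigma)), 2)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    r2 = xx**2 + yy**2
    k = (r2 - 2.0 * sigma**2) / sigma**4 * np.exp(-r2 / (2.0 * sigma**2))
    k /= 2.0 * np.pi * sigma**2
    return k - k.mean()


def wavelet_subbands(gray, mask=None, wavelet: str = "haar",
                     subbands=("L", "H")) -> dict[str, np.ndarray]:
    """Single-level undecimated 2-D wavelet decomposition.

    Returns a dict mapping subband names to same-shape images:
    ``"L"`` is the approximation (LL) subband and ``"H"`` the diagonal
    detail (HH) subband; ``"LH"``/``"HL"`` are available on request.
    Odd dimensions are mirror-padded to even before the stationary
    transform and trimmed afterwards. With ``mask`` given, each subband is
    re-standardized to [0, 255] within the ROI.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2 or min(gray.shape) < 8:
        raise ValueError("image must be 2-D and at least 8x8")
    pad_r = gray.shape[0] % 2
    pad_c = gray.shape[1] % 2
    padded = np.pad(gray, ((0, pad_r), (0, pad_c)), mode="reflect")
    (cA, (cH, cV, cD)) = pywt.swt2(padded, wavelet, level=1, norm=False)[0]
    full = {"L": cA, "H": cD, "LH": cH, "HL": cV}
    out: dict[str, np.ndarray] = {}
    for name in subbands:
        if name not in full:
            raise ValueError(f"unknown subband {name!r}")
        band = full[name][: gray.shape[0], : gray.shape[1]]
        out[name] = band if mask is None else standardize_intensity(band, mask)
    return out


def quantize_gray_levels(gray, mask, ng: int = 32) -> QuantizedRoi:
    """Discretize within-ROI intensities into ``ng`` equal-width levels.

    Bins span the within-ROI [min, max]; the top edge is inclusive, so the
    maximum maps to level ``ng``. A constant ROI occupies level 1 only.
    The output is invariant to increasing affine intensity transforms
    because the bin edges rescale with the data.
    """
    if ng < 2:
        raise ValueError("ng must be at least 2")
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gray.shape:
        raise ValueError("mask shape must equal image shape")
    if not mask.any():
        raise ValueError("empty mask")
    vals = gray[mask]
    lo, hi = float(vals.min()), float(vals.max())
    edges = np.linspace(lo, hi, ng + 1)
    levels = np.zeros(gray.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
    else:
        # searchsorted on interior edges: value==edge goes to the upper bin,
        # the maximum lands in bin ng (top edge inclusive).
        lv = np.searchsorted(edges[1:-1], vals, side="right") + 1
        levels[mask] = lv.astype(np.int32)
    return QuantizedRoi(levels=levels, mask=mask, ng=ng, bin_edges=edges)


def estimate_resolution_fwhm(edge_image, edge_axis: int, pixel_pitch: float) -> float:
    """Spatial resolution from a step-edge target, in the pitch's units.

    The edge-spread function (ESF) is the mean profile taken perpendicular
    to an edge aligned with ``edge_axis`` (0: edge runs along rows, profiles
    along columns; 1: the transpose). Differentiating the ESF gives the
    line-spread function (LSF); the result is its full width at half
    maximum, located by linear interpolation at the half-maximum level on
    each flank, times ``pixel_pitch``. For a Gaussian blur of width sigma
    the expected value is 2.3548 * sigma * pitch.
    """
    img = np.asarray(edge_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("edge image must be 2-D")
    if pixel_pitch <= 0:
        raise ValueError("pixel pitch must be positive")
    if edge_axis == 0:
        esf = img.mean(axis=0)
    elif edge_axis == 1:
        esf = img.mean(axis=1)
    else:
        raise ValueError("edge_axis must be 0 or 1")
    span = esf.max() - esf.min()
    if span <= 0:
        raise ValueError("no detectable edge: flat profile")
    # Dominant-edge check: the net excursion must dominate the total variation.
    tv = np.abs(np.diff(esf)).sum()
    if abs(esf[-1] - esf[0]) < 0.5 * tv:
        raise ValueError("no single dominant monotonic edge detected")
    # LSF by finite differences (samples live at half-integer positions),
    # upsampled with a cubic spline so the half-maximum crossings are
    # located sub-pixel without the coarse-grid interpolation bias.
    from scipy.interpolate import CubicSpline

    lsf_px = np.diff(esf)
    x = np.arange(lsf_px.size, dtype=float) + 0.5
    step = 0.02
    xf = np.arange(x[0], x[-1] + step / 2, step)
    lsf = np.abs(CubicSpline(x, lsf_px)(xf))
    k = int(np.argmax(lsf))
    half = lsf[k] / 2.0
    # linear interpolation at the half-maximum level on each flank
    i = k
    while i > 0 and lsf[i - 1] >= half:
        i -= 1
    if i == 0:
        left = 0.0
    else:
        left = (i - 1) + (half - lsf[i - 1]) / (lsf[i] - lsf[i - 1])
    j = k
    while j < lsf.size - 1 and lsf[j + 1] >= half:
        j += 1
    if j == lsf.size - 1:
        right = float(lsf.size - 1)
    else:
        right = j + (lsf[j] - half) / (lsf[j] - lsf[j + 1])
    fwhm_px = max((right - left) * step, 1.0)  # 1 px discretization floor
    return float(fwhm_px * pixel_pitch)
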