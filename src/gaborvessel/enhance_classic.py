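"""Non-adaptive contrast enhancement: adaptive gamma correction with
distributed weights (GCADW), homomorphic filtering, joint equalization of
histogram (JEH), and plain unsharp masking.

All four operators take and return 2-D intensity fields in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_core import GrayImage, quantize_levels, validate_gray

__all__ = [
    "GcadwConfig",
    "HomomorphicConfig",
    "JehWorkspace",
    "UnsharpConfig",
    "compute_weighted_cdf",
    "gcadw_enhance",
    "homomorphic_transfer",
    "homomorphic_enhance",
    "neighborhood_mean",
    "jeh_equalized_level",
    "jeh_workspace",
    "jeh_equalize",
    "unsharp_enhance",
]


# ---------------------------------------------------------------------------
# GCADW: gamma corrected adaptively with distributed weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GcadwConfig:
    """Weighting-distribution exponent ``a`` and histogram resolution.

    ``a`` tempers how strongly the histogram shape modulates the
    per-level gamma; the default 0.5 follows the adaptive-gamma-correction
    literature the method derives from.
    """

    a: float = 0.5
    n_levels: int = 256

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("weighting exponent a must be positive")


def compute_weighted_cdf(histogram: np.ndarray, config: GcadwConfig | None = None) -> np.ndarray:
    """Weighted cumulative distribution over intensity levels.

    The pdf is reweighted as
    ``pdf_w = pdf_max * ((pdf - pdf_min) / (pdf_max - pdf_min))**a``
    with pdf_min/pdf_max taken over all levels, then accumulated and
    normalized so the last occupied level maps to 1.  A flat histogram
    (pdf_max == pdf_min) makes the weighting 0/0; it falls back to the
    plain unweighted cdf, the no-weighting limit.
    """
    config = config or GcadwConfig()
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or hist.size != config.n_levels:
        raise ValueError(f"expected a {config.n_levels}-level histogram")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    total = hist.sum()
    if total == 0:
        raise ValueError("all-zero histogram")
    pdf = hist / total
    pdf_max, pdf_min = pdf.max(), pdf.min()
    if pdf_max > pdf_min:
        pdf_w = pdf_max * ((pdf - pdf_min) / (pdf_max - pdf_min)) ** config.a
    else:
        pdf_w = pdf
    return np.cumsum(pdf_w) / pdf_w.sum()


def gcadw_enhance(img: GrayImage, config: GcadwConfig | None = None) -> GrayImage:
    """Adaptive gamma correction: level l maps to
    ``T(l) = l_max * (l / l_max)**(1 - cdf_w(l))``.

    The per-level exponent shrinks toward 0 for bright levels, lifting
    dark regions without compressing the bright end.  The mapping is
    monotone non-decreasing in l.
    """
    config = config or GcadwConfig()
    img = validate_gray(img)
    levels = quantize_levels(img, config.n_levels)
    hist = np.bincount(levels.ravel(), minlength=config.n_levels)
    cdf_w = compute_weighted_cdf(hist, config)
    l_max = int(levels.max())
    if l_max == 0:
        return img.copy()
    l = np.arange(config.n_levels, dtype=float)
    gamma = 1.0 - cdf_w
    with np.errstate(divide="ignore"):
        mapped = l_max * (l / l_max) ** gamma
    mapped[(l == 0) & (gamma == 0)] = l_max  # 0^0 limit: flat cdf mass at top
    return mapped[levels] / (config.n_levels - 1)


# ---------------------------------------------------------------------------
# Homomorphic filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomomorphicConfig:
    """Log-domain high-emphasis filter parameters.

    gamma_high/gamma_low are the high/low frequency gains (must satisfy
    gamma_high > gamma_low > 0 so reflectance is emphasized relative to
    illumination), steepness_k the exponent constant, cutoff_p0 the
    cutoff radius in frequency-index units (None: 0.05 * min(H, W),
    resolved per image).
    """

    gamma_high: float = 0.8
    gamma_low: float = 0.6
    steepness_k: float = 1.0
    cutoff_p0: float | None = None
    log_epsilon: float = 1.0 / 255.0

    def __post_init__(self) -> None:
        if not (self.gamma_high > self.gamma_low > 0):
            raise ValueError("require gamma_high > gamma_low > 0")
        if self.cutoff_p0 is not None and self.cutoff_p0 <= 0:
            raise ValueError("cutoff_p0 must be positive")

    def resolve_cutoff(self, shape: tuple[int, int]) -> float:
        if self.cutoff_p0 is not None:
            return self.cutoff_p0
        return 0.05 * min(shape)


def homomorphic_transfer(p: np.ndarray, config: HomomorphicConfig, p0: float) -> np.ndarray:
    """H(P) = (gh - gl) * (1 - exp(-k P^2 / P0^2)) + gl.

    Monotone non-decreasing in the frequency radius P: H(0) = gamma_low,
    H(inf) -> gamma_high.
    """
    p = np.asarray(p, dtype=float)
    g_h, g_l = config.gamma_high, config.gamma_low
    return (g_h - g_l) * (1.0 - np.exp(-config.steepness_k * p**2 / p0**2)) + g_l


def homomorphic_enhance(img: GrayImage, config: HomomorphicConfig | None = None) -> GrayImage:
    """Illumination-flattening enhancement.

    log(img + eps) -> 2-D FFT -> multiply by the high-emphasis transfer
    function -> inverse FFT -> exp -> subtract eps -> min-max rescale.
    Attenuating low frequencies in the log domain suppresses the
    multiplicative illumination component relative to reflectance.
    """
    config = config or HomomorphicConfig()
    img = validate_gray(img)
    h, w = img.shape
    p0 = config.resolve_cutoff(img.shape)

    logged = np.log(img + config.log_epsilon)
    spectrum = np.fft.fft2(logged)
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    filtered = np.fft.ifft2(spectrum * homomorphic_transfer(radius, config, p0)).real
    out = np.exp(filtered) - config.log_epsilon

    lo, hi = out.min(), out.max()
    if hi - lo <= 1e-12:
        return np.clip(out, 0.0, 1.0)
    return (out - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# JEH: joint equalization of histogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JehWorkspace:
    """Intermediate state of joint histogram equalization.

    joint_histogram counts pair occurrences h(a, b) of (pixel level,
    neighborhood-mean level); cdf2d is its 2-D cumulative sum; cdf_min
    the minimum CDF over pairs that occur; mapping the pair -> output
    level table (-1 for pairs that never occur).
    """

    window_z: int
    joint_histogram: np.ndarray
    cdf2d: np.ndarray
    cdf_min: int
    mapping: np.ndarray


def neighborhood_mean(img: GrayImage, window_z: int = 3) -> GrayImage:
    """Mean over the Z x Z window around each pixel, replicate padding."""
    if window_z < 3 or window_z % 2 == 0:
        raise ValueError("window_z must be odd and >= 3")
    img = validate_gray(img)
    # uniform_filter can drift a few ulp outside [0, 1]; clip the roundoff
    return np.clip(ndimage.uniform_filter(img, size=window_z, mode="nearest"), 0.0, 1.0)


def jeh_equalized_level(cdf: int, cdf_min: int, n_pixels: int, n_levels: int = 256) -> int:
    """Output level of one pixel pair: trunc((L-1) (CDF - CDF_min) / (MN - 1)).

    Truncation toward zero is the integer-conversion convention (e.g. a
    pair with CDF 11 and CDF_min 1 in a 36-pixel image maps to
    trunc(10/35 * 255) = 72).
    """
    return int((n_levels - 1) * (cdf - cdf_min) / (n_pixels - 1))


def jeh_workspace(img: GrayImage, window_z: int = 3, n_levels: int = 256) -> JehWorkspace:
    """Build the joint histogram, 2-D CDF and pair -> level mapping."""
    img = validate_gray(img)
    f = quantize_levels(img, n_levels)
    g = quantize_levels(neighborhood_mean(img, window_z), n_levels)

    flat = f.ravel() * n_levels + g.ravel()
    joint = np.bincount(flat, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    cdf2d = joint.cumsum(axis=0).cumsum(axis=1)

    occurring = joint > 0
    cdf_min = int(cdf2d[occurring].min())
    n_pixels = img.size
    mapping = np.full((n_levels, n_levels), -1, dtype=np.int64)
    mapping[occurring] = (
        (n_levels - 1) * (cdf2d[occurring] - cdf_min) // (n_pixels - 1)
        if n_pixels > 1
        else 0
    )
    return JehWorkspace(window_z, joint, cdf2d, cdf_min, mapping)


def jeh_equalize(img: GrayImage, window_z: int = 3) -> GrayImage:
    """Joint equalization of histogram.

    Each pixel is keyed by the pair (its own 8-bit level, the 8-bit
    level of its Z x Z neighborhood mean); the 2-D CDF of pair counts
    drives an equalization mapping, so pixels with identical pairs
    receive identical output levels.  Output is the mapped level / 255.
    """
    img = validate_gray(img)
    ws = jeh_workspace(img, window_z)
    n_levels = ws.joint_histogram.shape[0]
    f = quantize_levels(img, n_levels)
    g = quantize_levels(neighborhood_mean(img, window_z), n_levels)
    return ws.mapping[f, g] / (n_levels - 1)


# ---------------------------------------------------------------------------
# Unsharp masking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnsharpConfig:
    """Gain ``k`` in [0.2, 0.7] (higher = more sharpening) and the
    Gaussian sigma of the smoothing that defines the mask."""

    gain_k: float = 0.5
    smooth_sigma: float = 2.0
    allow_gain_outside_range: bool = False

    def __post_init__(self) -> None:
        if not self.allow_gain_outside_range and not (0.2 <= self.gain_k <= 0.7):
            raise ValueError("gain_k must lie in [0.2, 0.7]")
        if self.smooth_sigma <= 0:
            raise ValueError("smooth_sigma must be positive")


def unsharp_enhance(img: GrayImage, config: UnsharpConfig | None = None) -> GrayImage:
    """Add back a scaled high-frequency residual:
    out = clip(img + k * (img - gaussian(img)), 0, 1)."""
    config = config or UnsharpConfig()
    img = validate_gray(img)
    residual = img - ndimage.gaussian_filter(img, config.smooth_sigma, mode="nearest")
    return np.clip(img + config.gain_k * residual, 0.0, 1.0)
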