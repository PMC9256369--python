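"""Hysteresis thresholding, morphological cleaning, and the end-to-end
enhancement -> Gabor -> threshold segmentation pipeline.

Thresholds are percentile-based over the field of view so one default
spans differently scaled responses; a pixel survives hysteresis iff it
is above the low threshold and connected (4- or 8-connectivity) through
above-low pixels to some above-high pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects

from . import enhance_classic as ec
from .enhance_adaptive_usm import AdaptiveUsmConfig, adaptive_usm_enhance_gray
from .enhance_pso_usm import PsoConfig, pso_usm_enhance
from .gabor_bank import GaborBankConfig, gabor_max_response
from .imaging_core import BinaryMask, GrayImage, RgbImage, extract_green_channel, validate_gray

__all__ = [
    "ENHANCEMENT_METHODS",
    "SegmentationConfig",
    "hysteresis_threshold",
    "morphological_clean",
    "enhance_gray",
    "segment_vessels",
]

ENHANCEMENT_METHODS = (
    "none",
    "gcadw",
    "homomorphic",
    "jeh",
    "usm",
    "adaptive_usm",
    "pso_usm",
)


@dataclass(frozen=True)
class SegmentationConfig:
    """Pipeline configuration.

    ``method`` selects the enhancement applied to the green channel
    before the Gabor bank; hysteresis thresholds are percentiles of the
    in-FOV Gabor response; components smaller than
    ``min_component_area`` pixels are removed afterwards.
    """

    method: str = "none"
    high_percentile: float = 92.0
    low_percentile: float = 75.0
    min_component_area: int = 30
    connectivity: int = 8
    gabor: GaborBankConfig = field(default_factory=GaborBankConfig)
    gcadw: ec.GcadwConfig = field(default_factory=ec.GcadwConfig)
    homomorphic: ec.HomomorphicConfig = field(default_factory=ec.HomomorphicConfig)
    jeh_window: int = 3
    unsharp: ec.UnsharpConfig = field(default_factory=ec.UnsharpConfig)
    adaptive_usm: AdaptiveUsmConfig = field(default_factory=AdaptiveUsmConfig)
    pso: PsoConfig = field(default_factory=PsoConfig)

    def __post_init__(self) -> None:
        if self.method not in ENHANCEMENT_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {ENHANCEMENT_METHODS}"
            )
        if not (0 < self.low_percentile < self.high_percentile < 100):
            raise ValueError("require 0 < low_percentile < high_percentile < 100")
        if self.min_component_area < 1:
            raise ValueError("min_component_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def hysteresis_threshold(
    response: GrayImage, low: float, high: float, connectivity: int = 8
) -> BinaryMask:
    """Two-threshold segmentation.

    Keeps every above-low pixel whose above-low connected component
    contains at least one above-high pixel (thresholds are inclusive).
    """
    if low > high:
        raise ValueError("low threshold must not exceed high threshold")
    response = validate_gray(response)
    weak = response >= low
    strong = response >= high
    labels, n = ndimage.label(weak, structure=_structure(connectivity))
    if n == 0:
        return np.zeros_like(weak)
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return keep[labels]


def morphological_clean(
    mask: BinaryMask, min_component_area: int = 30, connectivity: int = 8
) -> BinaryMask:
    """Remove connected components smaller than ``min_component_area``
    pixels; components at or above the threshold are kept intact.
    Idempotent."""
    mask = np.asarray(mask, dtype=bool)
    if min_component_area <= 1:
        return mask.copy()
    # max_size removes components with area <= max_size, so components of
    # exactly min_component_area pixels are kept.
    return remove_small_objects(
        mask, max_size=min_component_area - 1, connectivity=2 if connectivity == 8 else 1
    )


def enhance_gray(
    gray: GrayImage, config: SegmentationConfig, seed: int | None = None
) -> GrayImage:
    """Apply the configured enhancement operator to a single channel."""
    method = config.method
    if method == "none":
        return validate_gray(gray)
    if method == "gcadw":
        return ec.gcadw_enhance(gray, config.gcadw)
    if method == "homomorphic":
        return ec.homomorphic_enhance(gray, config.homomorphic)
    if method == "jeh":
        return ec.jeh_equalize(gray, config.jeh_window)
    if method == "usm":
        return ec.unsharp_enhance(gray, config.unsharp)
    if method == "adaptive_usm":
        return adaptive_usm_enhance_gray(gray, config.adaptive_usm)
    if method == "pso_usm":
        pso = config.pso if seed is None else replace(config.pso, seed=seed)
        return pso_usm_enhance(gray, pso)
    raise ValueError(f"unknown method {method!r}")


def segment_vessels(
    img: RgbImage,
    config: SegmentationConfig | None = None,
    fov: BinaryMask | None = None,
    seed: int | None = None,
) -> BinaryMask:
    """End-to-end vessel segmentation.

    Green channel -> enhancement -> maximum Gabor response (rescaled
    over the FOV) -> hysteresis at the configured response percentiles
    -> small-component removal -> restriction to the FOV.  Fully
    deterministic for a fixed seed, including the PSO method.
    """
    config = config or SegmentationConfig()
    if config.method == "pso_usm" and seed is None:
        seed = config.pso.seed
    gray = extract_green_channel(img)
    enhanced = enhance_gray(gray, config, seed)
    response = gabor_max_response(enhanced, config.gabor, fov=fov)

    region = response[np.asarray(fov, dtype=bool)] if fov is not None else response
    low = float(np.percentile(region, config.low_percentile))
    high = float(np.percentile(region, config.high_percentile))
    mask = hysteresis_threshold(response, low, high, config.connectivity)
    mask = morphological_clean(mask, config.min_component_area, config.connectivity)
    if fov is not None:
        mask = mask & np.asarray(fov, dtype=bool)
    return mask
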