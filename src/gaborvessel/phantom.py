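"""Seeded synthetic fundus phantoms.

Each phantom is a reddish background under a radial illumination
falloff, carrying dark curvilinear branching vessel trees inside a
circular field of view, with additive Gaussian noise — enough structure
to exercise every stage of the enhancement / Gabor / threshold pipeline
without real fundus data.  Ground-truth vessel and FOV masks are exact
(the vessel mask is the rasterization before noise).

What the phantoms do NOT emulate: optic disc, fovea, lesions, the
central vessel reflex, and the intensity statistics of real fundus
cameras; green tests on phantoms establish pipeline correctness and
relative method ordering, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .imaging_core import BinaryMask, RgbImage

__all__ = ["PhantomConfig", "generate_phantom", "generate_phantom_set"]

_BACKGROUND_RGB = (0.75, 0.45, 0.25)  # reddish fundus tone before vignetting


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry and statistics.

    Vessels grow as random-walk polylines: ``n_trees`` roots enter near
    the FOV rim, branch ``branch_depth`` times, each child narrowed by
    ``width_decay``.  ``vessel_contrast`` is how much the green (and
    red) channel is depressed on vessels; ``vignette_strength`` the
    amplitude of the radial illumination falloff; ``noise_sd`` the
    additive Gaussian noise sigma.
    """

    height: int = 256
    width: int = 256
    n_trees: int = 3
    branch_depth: int = 4
    width_root: float = 4.0
    width_decay: float = 0.8
    vessel_contrast: float = 0.25
    vignette_strength: float = 0.3
    noise_sd: float = 0.02
    fov_radius_frac: float = 0.48
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.n_trees, self.branch_depth) < 1:
            raise ValueError("geometry parameters must be positive")
        if self.width_root <= 0 or self.width_decay <= 0:
            raise ValueError("vessel widths must be positive")
        for name in ("vessel_contrast", "vignette_strength", "noise_sd", "fov_radius_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def _stamp_disk(mask: np.ndarray, r: float, c: float, radius: float) -> None:
    """Set mask pixels within ``radius`` of (r, c), in place."""
    h, w = mask.shape
    rad = max(radius, 0.5)
    r0, r1 = max(int(r - rad) - 1, 0), min(int(r + rad) + 2, h)
    c0, c1 = max(int(c - rad) - 1, 0), min(int(c + rad) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - r
    cc = np.arange(c0, c1)[None, :] - c
    mask[r0:r1, c0:c1] |= rr * rr + cc * cc <= rad * rad


def _grow_branch(
    rng: np.random.Generator,
    mask: np.ndarray,
    pos: np.ndarray,
    heading: float,
    width: float,
    level: int,
    config: PhantomConfig,
) -> None:
    # Branch length shrinks with depth; heading wanders smoothly.
    n_steps = max(8, int(40 * 0.85**level))
    step = 2.0
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.12)
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        if not (0 <= pos[0] < config.height and 0 <= pos[1] < config.width):
            return
        _stamp_disk(mask, pos[0], pos[1], width / 2.0)
    if level + 1 < config.branch_depth:
        spread = 0.35 + abs(rng.normal(0.0, 0.1))
        for sign in (-1.0, 1.0):
            _grow_branch(
                rng,
                mask,
                pos.copy(),
                heading + sign * spread,
                width * config.width_decay,
                level + 1,
                config,
            )


def generate_phantom(config: PhantomConfig | None = None) -> tuple[RgbImage, BinaryMask, BinaryMask]:
    """Generate one phantom: (image, vessel mask, FOV mask).

    Identical configs (including seed) produce bit-identical triples.
    The vessel mask is clipped to the FOV, so the ground truth is
    always inside the imaged disc.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width

    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    dist = np.sqrt(rows**2 + cols**2)
    fov_radius = config.fov_radius_frac * min(h, w)
    fov = dist <= fov_radius

    vessels = np.zeros((h, w), dtype=bool)
    for _ in range(config.n_trees):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        start = center + 0.85 * fov_radius * np.array([np.sin(theta), np.cos(theta)])
        heading = theta + np.pi + rng.normal(0.0, 0.3)  # inward, with jitter
        _grow_branch(rng, vessels, start, heading, config.width_root, 0, config)
    vessels &= fov

    vignette = 1.0 - config.vignette_strength * np.clip(dist / (min(h, w) / 2.0), 0.0, 1.0) ** 2
    channels = []
    for i, base in enumerate(_BACKGROUND_RGB):
        plane = base * vignette
        if i < 2:  # vessels darken the red and green channels
            plane = plane - config.vessel_contrast * vessels
        channels.append(plane)
    arr = np.stack(channels, axis=-1)
    arr = arr + rng.normal(0.0, config.noise_sd, size=arr.shape)
    img = RgbImage.from_array(np.clip(arr, 0.0, 1.0))
    return img, vessels, fov


def generate_phantom_set(
    n: int, base_config: PhantomConfig | None = None
) -> list[tuple[RgbImage, BinaryMask, BinaryMask]]:
    """Generate ``n`` phantoms; phantom i uses seed = base seed + i, so
    each element is independently reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base_config = base_config or PhantomConfig()
    return [generate_phantom(replace(base_config, seed=base_config.seed + i)) for i in range(n)]
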