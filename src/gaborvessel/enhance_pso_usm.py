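"""Particle-swarm optimized unsharp masking.

A symmetric 3x3 edge-extraction kernel (3 free weights: centre, edge,
corner) and an augmentation gain are tuned by global-best PSO to
maximize the Shannon entropy of the enhanced image, penalized by the
fraction of pixels the raw enhancement pushes outside [0, 1] (the
over-range ratio).  The search is 4-dimensional and fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .enhance_adaptive_usm import shannon_entropy
from .imaging_core import GrayImage, validate_gray

__all__ = [
    "KernelSpec",
    "PsoConfig",
    "Particle",
    "expand_kernel",
    "usm_apply",
    "fitness",
    "pso_maximize",
    "pso_optimize",
    "pso_usm_enhance",
    "pso_usm_enhance_rgb",
]

IDENTITY_SPEC_POSITION = np.array([1.0, 0.0, 0.0, 0.0])  # centre, edge, corner, gain


@dataclass(frozen=True)
class KernelSpec:
    """Symmetric 3x3 kernel (8-fold symmetry) plus gain.

    ``center`` fills the middle cell, ``edge`` the four edge-adjacent
    cells, ``corner`` the four corners.
    """

    center: float
    edge: float
    corner: float
    gain: float

    @classmethod
    def from_vector(cls, x: Sequence[float]) -> "KernelSpec":
        return cls(*(float(v) for v in x))

    def to_vector(self) -> np.ndarray:
        return np.array([self.center, self.edge, self.corner, self.gain])


@dataclass(frozen=True)
class PsoConfig:
    """Canonical global-best PSO hyperparameters.

    Inertia / acceleration defaults are the Clerc-constriction
    equivalents (w = 0.729, c1 = c2 = 1.49445).  Bounds: kernel weights
    in [-2, 2], gain in [0, 2].  penalty_beta weights the over-range
    ratio in the fitness.
    """

    swarm_size: int = 30
    max_iterations: int = 100
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    kernel_bound: float = 2.0
    gain_bound: float = 2.0
    penalty_beta: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.cognitive < 0 or self.social < 0:
            raise ValueError("acceleration coefficients must be >= 0")

    def bounds(self) -> np.ndarray:
        kb, gb = self.kernel_bound, self.gain_bound
        return np.array([[-kb, kb], [-kb, kb], [-kb, kb], [0.0, gb]])


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    personal_best_position: np.ndarray
    personal_best_fitness: float


def expand_kernel(spec: KernelSpec) -> np.ndarray:
    """[[corner, edge, corner], [edge, center, edge], [corner, edge, corner]];
    equal to its transpose and any 90-degree rotation by construction."""
    c, e, k = spec.center, spec.edge, spec.corner
    return np.array([[k, e, k], [e, c, e], [k, e, k]])


def usm_apply(img: GrayImage, spec: KernelSpec) -> tuple[GrayImage, float]:
    """Apply the unsharp step: raw = img + gain * conv(img, kernel).

    Returns the clipped image and the over-range ratio, the fraction of
    pixels the raw result pushed outside [0, 1].
    """
    img = validate_gray(img)
    edge = ndimage.convolve(img, expand_kernel(spec), mode="reflect")
    raw = img + spec.gain * edge
    over = float(np.mean((raw < 0.0) | (raw > 1.0)))
    return np.clip(raw, 0.0, 1.0), over


def fitness(img: GrayImage, spec: KernelSpec, config: PsoConfig | None = None) -> float:
    """Entropy (bits, 256 bins) of the enhanced image minus
    penalty_beta times the over-range ratio."""
    config = config or PsoConfig()
    enhanced, over = usm_apply(img, spec)
    return shannon_entropy(enhanced) - config.penalty_beta * over


def pso_maximize(
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    config: PsoConfig | None = None,
    pinned_positions: Sequence[np.ndarray] = (),
) -> tuple[np.ndarray, float, np.ndarray]:
    """Global-best PSO over a box.

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x);  x <- clip(x + v).
    ``pinned_positions`` are injected into the initial swarm (replacing
    random initializations), so the returned best provably dominates
    them.  Returns (best position, best fitness, per-iteration trace of
    the global best); the trace is non-decreasing and identical seeds
    give identical runs.
    """
    config = config or PsoConfig()
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    dim = bounds.shape[0]
    rng = np.random.default_rng(config.seed)

    positions = rng.uniform(lo, hi, size=(config.swarm_size, dim))
    for i, pin in enumerate(pinned_positions[: config.swarm_size]):
        positions[i] = np.clip(np.asarray(pin, dtype=float), lo, hi)
    span = hi - lo
    velocities = rng.uniform(-span, span, size=(config.swarm_size, dim))

    fitnesses = np.array([objective(p) for p in positions])
    pbest = positions.copy()
    pbest_fit = fitnesses.copy()
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    trace = np.empty(config.max_iterations)
    for it in range(config.max_iterations):
        r1 = rng.random((config.swarm_size, dim))
        r2 = rng.random((config.swarm_size, dim))
        velocities = (
            config.inertia * velocities
            + config.cognitive * r1 * (pbest - positions)
            + config.social * r2 * (gbest - positions)
        )
        positions = np.clip(positions + velocities, lo, hi)
        fitnesses = np.array([objective(p) for p in positions])
        improved = fitnesses > pbest_fit
        pbest[improved] = positions[improved]
        pbest_fit[improved] = fitnesses[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        trace[it] = gbest_fit
    return gbest, gbest_fit, trace


def pso_optimize(img: GrayImage, config: PsoConfig | None = None) -> tuple[KernelSpec, np.ndarray]:
    """Tune the symmetric kernel and gain on ``img``.

    The identity spec (centre 1, gain 0: no enhancement) is pinned into
    the initial swarm, so fitness(best) >= fitness(identity) always.
    Returns the best KernelSpec and the best-fitness trace.
    """
    config = config or PsoConfig()
    img = validate_gray(img)

    def objective(x: np.ndarray) -> float:
        return fitness(img, KernelSpec.from_vector(x), config)

    best, _, trace = pso_maximize(
        objective, config.bounds(), config, pinned_positions=[IDENTITY_SPEC_POSITION]
    )
    return KernelSpec.from_vector(best), trace


def pso_usm_enhance(img: GrayImage, config: PsoConfig | None = None) -> GrayImage:
    """Run the PSO search and apply the winning kernel/gain."""
    spec, _ = pso_optimize(img, config)
    enhanced, _ = usm_apply(img, spec)
    return enhanced


def pso_usm_enhance_rgb(img, config: PsoConfig | None = None):
    """Standalone colour entry point: enhance the V channel in HSV space
    and convert back (the single-channel pipeline path operates on the
    green channel directly instead)."""
    from skimage.color import hsv2rgb, rgb2hsv

    from .imaging_core import RgbImage

    hsv = rgb2hsv(img.to_array())
    hsv[..., 2] = pso_usm_enhance(np.clip(hsv[..., 2], 0.0, 1.0), config)
    return RgbImage.from_array(np.clip(hsv2rgb(hsv), 0.0, 1.0))
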