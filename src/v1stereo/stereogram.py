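"""Seeded random-dot stereogram (RDS) generators with ground-truth disparity.

Three disparity profiles on 200x200 images probe small (1 px) and large
(5 px) disparities:

* ``square`` — a centred 100x100 region at +5 px over a -1 px surround
  (a step-edge depth profile);
* ``ramp`` — a centred 160x160 region whose disparity ramps linearly from
  -5 to +5 px across columns over a 0 px surround;
* ``gabor_surface`` — a smooth corrugation, 5 px times a 2D Gabor surface;
* ``uniform`` — a constant-disparity field (calibration stimulus).

A stereogram is a binary dot field (the left image) plus a warped copy: the
right image samples the dots at ``x - d(x, y)`` with linear interpolation,
so right-image content is displaced by +d relative to left.  Samples
falling outside the field are refilled with fresh seeded dots (no
wraparound).  The (kind, seed, parameters) triple fully determines the
stereogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DEFAULT_SIZE = 200
DEFAULT_DENSITY = 0.5

KINDS = ("square", "ramp", "gabor_surface", "uniform")


@dataclass(frozen=True)
class GroundTruthStereogram:
    left: np.ndarray = field(repr=False)
    right: np.ndarray = field(repr=False)
    truth: np.ndarray = field(repr=False)
    kind: str
    seed: int

    def __post_init__(self) -> None:
        if not (self.left.shape == self.right.shape == self.truth.shape):
            raise ValueError("left/right/truth shapes differ")
        if not np.isfinite(self.truth).all():
            raise ValueError("truth map contains non-finite values")


def random_dot_field(width: int, height: int, density: float = DEFAULT_DENSITY,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Binary dot image with P(dot) = density, reproducible per seed."""
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must be in (0, 1), got {density}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return (rng.random((height, width)) < density).astype(float)


def disparity_profile_square(size: int = DEFAULT_SIZE, region: int | None = None,
                             center_px: float = 5.0, surround_px: float = -1.0
                             ) -> np.ndarray:
    """Centred ``region x region`` block at +5 px over a -1 px surround.

    The region defaults to half the image side (100 px at the standard
    200 px size)."""
    region = size // 2 if region is None else region
    if not 0 < region < size:
        raise ValueError(f"region {region} does not fit a {size} px image")
    truth = np.full((size, size), surround_px)
    lo = (size - region) // 2
    truth[lo:lo + region, lo:lo + region] = center_px
    return truth


def disparity_profile_ramp(size: int = DEFAULT_SIZE, region: int | None = None,
                           d_min: float = -5.0, d_max: float = 5.0) -> np.ndarray:
    """Centred region ramping linearly across columns, zero surround.

    The region defaults to 4/5 of the image side (160 px at the standard
    200 px size)."""
    region = 4 * size // 5 if region is None else region
    if not 0 < region < size:
        raise ValueError(f"region {region} does not fit a {size} px image")
    truth = np.zeros((size, size))
    lo = (size - region) // 2
    ramp = np.linspace(d_min, d_max, region)
    truth[lo:lo + region, lo:lo + region] = ramp[None, :]
    return truth


def disparity_profile_gabor(size: int = DEFAULT_SIZE, amplitude_px: float = 5.0,
                            frequency_cpd: float = 0.4,
                            pixels_per_degree: float = 40.0,
                            sigma_px: float = 40.0, orientation_deg: float = 0.0,
                            phase_rad: float = 0.0) -> np.ndarray:
    """Smooth surface: amplitude times a centred 2D Gabor function.

    ``G(x, y) = exp(-(x'^2 + y'^2) / (2 sigma^2)) * cos(2 pi f x' + phase)``
    with ``x'`` along ``orientation_deg`` and ``f`` converted from
    cycles/degree through ``pixels_per_degree``.  The surface is centred on
    pixel ``(size//2, size//2)`` so the peak |disparity| equals
    ``amplitude_px`` exactly (for zero phase).
    """
    f_px = frequency_cpd / pixels_per_degree
    c = size // 2
    y, x = np.mgrid[0:size, 0:size]
    theta = math.radians(orientation_deg)
    xr = (x - c) * math.cos(theta) + (y - c) * math.sin(theta)
    yr = -(x - c) * math.sin(theta) + (y - c) * math.cos(theta)
    envelope = np.exp(-(xr ** 2 + yr ** 2) / (2.0 * sigma_px ** 2))
    carrier = np.cos(2.0 * np.pi * f_px * xr + phase_rad)
    return amplitude_px * envelope * carrier


def warp(dots: np.ndarray, truth: np.ndarray, density: float = DEFAULT_DENSITY,
         rng: np.random.Generator | int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Build the (left, right) pair from a dot field and a disparity map.

    ``right(x, y) = dots(x - truth(x, y), y)`` with linear interpolation for
    fractional disparities; sample positions outside the image are refilled
    with fresh seeded dots (wraparound is forbidden).
    """
    dots = np.asarray(dots, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if dots.shape != truth.shape:
        raise ValueError("dots and truth shapes differ")
    h, w = dots.shape
    if np.abs(truth).max() >= w / 4:
        raise ValueError("disparity magnitude must stay below width/4")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    xs = np.arange(w)[None, :] - truth  # sample column per right-image pixel
    valid = (xs >= 0.0) & (xs <= w - 1)
    i0 = np.clip(np.floor(xs).astype(int), 0, w - 2)
    frac = np.clip(xs - i0, 0.0, 1.0)
    rows = np.arange(h)[:, None]
    right = (1.0 - frac) * dots[rows, i0] + frac * dots[rows, i0 + 1]
    n_refill = int((~valid).sum())
    if n_refill:
        right[~valid] = (rng.random(n_refill) < density).astype(float)
    return dots.copy(), right


def make_stereogram(kind: str, seed: int, size: int = DEFAULT_SIZE,
                    density: float = DEFAULT_DENSITY,
                    uniform_disparity_px: float = 0.0,
                    gabor_params: dict | None = None) -> GroundTruthStereogram:
    """Generate one seeded stereogram of the requested kind."""
    if kind not in KINDS:
        raise ValueError(f"unknown stereogram kind {kind!r}; expected one of {KINDS}")
    rng = np.random.default_rng(seed)
    dots = random_dot_field(size, size, density, rng)
    if kind == "square":
        truth = disparity_profile_square(size)
    elif kind == "ramp":
        truth = disparity_profile_ramp(size)
    elif kind == "gabor_surface":
        truth = disparity_profile_gabor(size, **(gabor_params or {}))
    else:
        truth = np.full((size, size), float(uniform_disparity_px))
    left, right = warp(dots, truth, density, rng)
    return GroundTruthStereogram(left=left, right=right, truth=truth,
                                 kind=kind, seed=seed)
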