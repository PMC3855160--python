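"""Frequency-domain construction of log-Gabor and Gabor quadrature filter banks.

Filters model the receptive fields of binocular simple cells in primary
visual cortex (V1).  Each channel is the product of two polar-separable
terms on the discrete Fourier plane:

* an angular Gaussian centred on the channel orientation, and
* a radial envelope — Gaussian on a *logarithmic* frequency axis
  (log-Gabor family, zero DC at any bandwidth) or Gaussian on a linear
  frequency axis (Gabor family, whose DC leakage grows with bandwidth).

The quadrature (odd) partner of each even filter is its Hilbert transform
along the channel orientation: ``odd = i * sign(u·cosθ + v·sinθ) * even``.

All filters live on the *unshifted* DFT layout (DC at bin ``(0, 0)``) in
normalized frequency units (cycles/pixel, Nyquist = 0.5), so they multiply
directly with ``numpy.fft.fft2`` image spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Default angular standard deviation (radians), calibrated on the synthetic
#: random-dot benchmark (see docs/methods.md).  Narrow angular tuning widens
#: the receptive fields along their length, which steadies the pointwise
#: energy at the cost of extra blur across depth edges.
DEFAULT_ANGULAR_SIGMA_RAD = 0.25

#: Channel orientations (degrees, anticlockwise from the +u frequency axis).
LOG_GABOR_ORIENTATIONS_DEG = (30.0, 60.0, 90.0, 210.0, 240.0, 270.0)
GABOR_ORIENTATIONS_DEG = (30.0, 60.0, 90.0, 120.0, 150.0, 180.0)

#: Gabor-baseline centre frequencies in cycles/degree of visual angle.
GABOR_FREQUENCIES_CPD = (0.5, 1.0, 2.0, 4.0)

FAMILIES = ("log_gabor", "gabor")


# ---------------------------------------------------------------------------
# Frequency grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyGrid:
    """Polar coordinates of every bin of a 2D discrete Fourier plane.

    Attributes
    ----------
    width, height : int
        Image dimensions in pixels (columns, rows).
    radius : (height, width) ndarray
        Radial frequency rho in cycles/pixel; 0 exactly at the DC bin (0, 0).
    angle : (height, width) ndarray
        Anticlockwise angular coordinate phi in (-pi, pi], measured from the
        +u axis (one bin step along columns); +pi/2 one bin step along rows.
    ux : (width,) ndarray
        Horizontal frequencies (``numpy.fft.fftfreq`` order), used for the
        positional-shift phase ramps.
    vy : (height,) ndarray
        Vertical frequencies.
    """

    width: int
    height: int
    radius: np.ndarray = field(repr=False)
    angle: np.ndarray = field(repr=False)
    ux: np.ndarray = field(repr=False)
    vy: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


def build_frequency_grid(width: int, height: int) -> FrequencyGrid:
    """Build the polar frequency grid for a ``height x width`` image.

    The Cartesian-to-polar conversion is ``rho = hypot(u, v)`` and
    ``phi = atan2(v, u)`` with ``u = fftfreq(width)``, ``v = fftfreq(height)``
    in cycles/pixel.  DC sits at bin (0, 0) (unshifted spectrum layout).
    """
    if width < 8 or height < 8:
        raise ValueError(f"grid dimensions must be >= 8, got {width}x{height}")
    ux = np.fft.fftfreq(width)
    vy = np.fft.fftfreq(height)
    uu, vv = np.meshgrid(ux, vy)
    radius = np.hypot(uu, vv)
    angle = np.arctan2(vv, uu)
    return FrequencyGrid(width=width, height=height, radius=radius,
                         angle=angle, ux=ux, vy=vy)


# ---------------------------------------------------------------------------
# Channel specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """One (orientation, wavelength) filter definition.

    ``wavelength_px`` is the centre wavelength lambda; the centre frequency
    is ``f0 = 1/lambda`` cycles/pixel.  ``sigma_ratio`` is sigma_r/f0 of the
    radial log-Gaussian (0.65 gives ~1.5 octave bandwidth); for the Gabor
    family the linear-frequency sigma is derived from the same octave
    bandwidth so the two families match in nominal tuning width.
    """

    orientation_deg: float
    wavelength_px: float
    sigma_ratio: float = 0.65
    angular_sigma_rad: float = DEFAULT_ANGULAR_SIGMA_RAD

    def __post_init__(self) -> None:
        if self.wavelength_px < 2.0:
            raise ValueError(
                f"wavelength {self.wavelength_px} px is below the 2 px Nyquist limit")
        if not 0.0 < self.sigma_ratio < 1.0:
            raise ValueError(f"sigma_ratio must be in (0, 1), got {self.sigma_ratio}")
        if self.angular_sigma_rad <= 0.0:
            raise ValueError("angular_sigma_rad must be positive")

    @property
    def f0(self) -> float:
        """Centre frequency in cycles/pixel."""
        return 1.0 / self.wavelength_px

    @property
    def bandwidth_octaves(self) -> float:
        """Half-amplitude radial bandwidth implied by sigma_ratio."""
        c = math.sqrt(2.0 * math.log(2.0))
        return 2.0 * c * abs(math.log(self.sigma_ratio)) / math.log(2.0)


@dataclass(frozen=True)
class QuadratureFilter:
    """An even/odd (in-phase / Hilbert) transfer-function pair.

    ``even`` is real; ``odd = i * sign(projection) * even`` is purely
    imaginary.  Both are one-sided in frequency; real-valued simple-cell
    responses are recovered by taking the real part of the complex inverse
    transform (equivalently, by Hermitian-symmetrizing the transfer).
    """

    even: np.ndarray = field(repr=False)
    odd: np.ndarray = field(repr=False)
    family: str
    spec: ChannelSpec
    shape: tuple[int, int]


@dataclass(frozen=True)
class FilterBank:
    """Ordered channel list, coarsest (largest wavelength) first."""

    channels: tuple[ChannelSpec, ...]
    family: str

    def __post_init__(self) -> None:
        waves = [c.wavelength_px for c in self.channels]
        if waves != sorted(waves, reverse=True):
            raise ValueError("channels must be ordered coarsest-first")

    @property
    def wavelengths_px(self) -> tuple[float, ...]:
        seen: list[float] = []
        for c in self.channels:
            if c.wavelength_px not in seen:
                seen.append(c.wavelength_px)
        return tuple(seen)

    @property
    def orientations_deg(self) -> tuple[float, ...]:
        seen: list[float] = []
        for c in self.channels:
            if c.orientation_deg not in seen:
                seen.append(c.orientation_deg)
        return tuple(seen)


# ---------------------------------------------------------------------------
# Filter components
# ---------------------------------------------------------------------------

def angular_gaussian(grid: FrequencyGrid, orientation_deg: float,
                     angular_sigma_rad: float) -> np.ndarray:
    """Angular Gaussian envelope ``exp(-dtheta^2 / (2 sigma^2))``.

    The absolute angular distance ``dtheta`` between each bin's angle and
    the channel orientation is obtained from the sine/cosine difference in
    the rotated frame, ``atan2(sin(phi - theta), cos(phi - theta))``, which
    wraps correctly at +-pi.
    """
    if angular_sigma_rad <= 0.0:
        raise ValueError("angular sigma must be positive")
    theta = math.radians(orientation_deg)
    sin_phi, cos_phi = np.sin(grid.angle), np.cos(grid.angle)
    ds = sin_phi * math.cos(theta) - cos_phi * math.sin(theta)
    dc = cos_phi * math.cos(theta) + sin_phi * math.sin(theta)
    dtheta = np.abs(np.arctan2(ds, dc))
    return np.exp(-(dtheta ** 2) / (2.0 * angular_sigma_rad ** 2))


def radial_log_gabor(grid: FrequencyGrid, f0: float, sigma_ratio: float) -> np.ndarray:
    """Radial log-Gabor envelope: a Gaussian on a log frequency axis.

    ``w(rho) = exp(-(ln(rho/f0))^2 / (2 (ln sigma_ratio)^2))`` for rho > 0,
    with the DC bin set to exactly 0 (the log-Gabor has no DC component at
    any bandwidth).  Peak value 1 at rho = f0.
    """
    if not 0.0 < f0 < 0.5:
        raise ValueError(f"f0 must be in (0, 0.5) cycles/pixel, got {f0}")
    if not 0.0 < sigma_ratio < 1.0:
        raise ValueError(f"sigma_ratio must be in (0, 1), got {sigma_ratio}")
    rho = grid.radius
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-(np.log(rho / f0) ** 2) /
                   (2.0 * math.log(sigma_ratio) ** 2))
    w[rho == 0.0] = 0.0
    return w


def orientation_sign(grid: FrequencyGrid, orientation_deg: float) -> np.ndarray:
    """Sign of each bin's frequency projected on the channel direction.

    This is the sign function of the 2D Hilbert transform taken along the
    filter orientation; it is 0 on the line through DC perpendicular to the
    orientation.
    """
    theta = math.radians(orientation_deg)
    # snap the direction cosines so axis-aligned orientations put an exact
    # zero on the perpendicular frequency line (cos(pi/2) is not 0 in floats)
    ct, st = math.cos(theta), math.sin(theta)
    ct = 0.0 if abs(ct) < 1e-12 else ct
    st = 0.0 if abs(st) < 1e-12 else st
    uu, vv = np.meshgrid(grid.ux, grid.vy)
    return np.sign(uu * ct + vv * st)


def _below_nyquist(grid: FrequencyGrid) -> np.ndarray:
    # The Nyquist row/column of an even-sized DFT are their own negative
    # frequencies: a one-sided filter and its Hilbert partner are ill-defined
    # there, so filters are band-limited to the open interval (-0.5, 0.5).
    return ((np.abs(grid.vy) < 0.5)[:, None]
            & (np.abs(grid.ux) < 0.5)[None, :])


def compose_log_gabor(grid: FrequencyGrid, spec: ChannelSpec) -> QuadratureFilter:
    """Compose the 2D log-Gabor quadrature pair for one channel.

    Even transfer = angular Gaussian x radial log-Gabor; odd transfer is the
    Hilbert partner ``i * sign * even``.  Bins where the orientation
    projection is exactly zero (DC, and for axis-aligned orientations the
    perpendicular frequency line) are zeroed in both so the pair is in exact
    quadrature everywhere.
    """
    even = (angular_gaussian(grid, spec.orientation_deg, spec.angular_sigma_rad)
            * radial_log_gabor(grid, spec.f0, spec.sigma_ratio))
    s = orientation_sign(grid, spec.orientation_deg)
    even = np.where(s == 0.0, 0.0, even) * _below_nyquist(grid)
    odd = 1j * s * even
    return QuadratureFilter(even=even, odd=odd, family="log_gabor",
                            spec=spec, shape=grid.shape)


def _gabor_radial_sigma(f0: float, bandwidth_octaves: float) -> float:
    # linear-frequency Gaussian sigma giving the requested half-amplitude
    # octave bandwidth: beta = log2((f0 + c s)/(f0 - c s)), c = sqrt(2 ln 2)
    c = math.sqrt(2.0 * math.log(2.0))
    r = 2.0 ** bandwidth_octaves
    return f0 * (r - 1.0) / (r + 1.0) / c


def compose_gabor(grid: FrequencyGrid, spec: ChannelSpec) -> QuadratureFilter:
    """Compose the Gabor-baseline quadrature pair for one channel.

    The radial envelope is a Gaussian on a *linear* frequency axis,
    ``exp(-(rho - f0)^2 / (2 sigma_r^2))``, with sigma_r set from the same
    octave bandwidth as the log-Gabor family.  No DC correction is applied
    inside the filter: the even transfer keeps its nonzero weight at DC
    (``exp(-f0^2 / (2 sigma_r^2))``), the classical Gabor leak that the
    mean-luminance subtraction of the image only partially hides.  The odd
    partner is the Hilbert pair and has exactly zero DC.
    """
    f0 = spec.f0
    sigma_r = _gabor_radial_sigma(f0, spec.bandwidth_octaves)
    radial = np.exp(-((grid.radius - f0) ** 2) / (2.0 * sigma_r ** 2))
    even = (angular_gaussian(grid, spec.orientation_deg, spec.angular_sigma_rad)
            * radial) * _below_nyquist(grid)
    # the DC bin has no orientation: it carries the full radial weight
    even[0, 0] = radial[0, 0]
    odd = 1j * orientation_sign(grid, spec.orientation_deg) * even
    return QuadratureFilter(even=even, odd=odd, family="gabor",
                            spec=spec, shape=grid.shape)


def compose_filter(grid: FrequencyGrid, spec: ChannelSpec, family: str) -> QuadratureFilter:
    """Dispatch to the family's composer."""
    if family == "log_gabor":
        return compose_log_gabor(grid, spec)
    if family == "gabor":
        return compose_gabor(grid, spec)
    raise ValueError(f"unknown filter family {family!r}; expected one of {FAMILIES}")


def truncate_spatial_support(qf: QuadratureFilter, grid: FrequencyGrid,
                             window: tuple[int, int] = (49, 97)) -> QuadratureFilter:
    """Optionally restrict a filter's spatial kernel to a centred RF window.

    The kernel (inverse transform of each transfer) is windowed to
    ``window = (rows, cols)`` pixels around the origin and transformed back.
    Off by default in the pipeline; the frequency-domain construction is the
    primary mechanism and windowing slightly perturbs the quadrature
    relation.
    """
    rows, cols = window
    hr, hc = rows // 2, cols // 2
    dy = np.minimum(np.arange(grid.height), grid.height - np.arange(grid.height))
    dx = np.minimum(np.arange(grid.width), grid.width - np.arange(grid.width))
    mask = (dy[:, None] <= hr) & (dx[None, :] <= hc)

    def _windowed(weights: np.ndarray) -> np.ndarray:
        kernel = np.fft.ifft2(weights)
        return np.fft.fft2(kernel * mask)

    return QuadratureFilter(even=_windowed(qf.even), odd=_windowed(qf.odd),
                            family=qf.family, spec=qf.spec, shape=qf.shape)


# ---------------------------------------------------------------------------
# Bank construction
# ---------------------------------------------------------------------------

def make_filter_bank(
    family: str = "log_gabor",
    orientations_deg: tuple[float, ...] | None = None,
    n_scales: int = 4,
    lambda_min_px: float = 3.0,
    scale_factor: float = 1.6,
    sigma_ratio: float = 0.65,
    angular_sigma_rad: float = DEFAULT_ANGULAR_SIGMA_RAD,
    pixels_per_degree: float | None = 40.0,
    gabor_frequencies_cpd: tuple[float, ...] = GABOR_FREQUENCIES_CPD,
) -> FilterBank:
    """Build the channel list for one filter family, coarsest scale first.

    Log-Gabor wavelengths follow ``lambda_k = lambda_min * scale_factor**k``
    for ``k = 0..n_scales-1`` (defaults 3, 4.8, 7.68, 12.288 px).  Gabor
    centre frequencies are given in cycles/degree and converted to pixels
    through ``pixels_per_degree``.  Channels are ordered scale-major
    (coarse to fine), orientation-minor, as required by the coarse-to-fine
    disparity search.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown filter family {family!r}")
    if orientations_deg is None:
        orientations_deg = (LOG_GABOR_ORIENTATIONS_DEG if family == "log_gabor"
                            else GABOR_ORIENTATIONS_DEG)
    if family == "log_gabor":
        if n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        wavelengths = [lambda_min_px * scale_factor ** k for k in range(n_scales)]
    else:
        if pixels_per_degree is None:
            raise ValueError("pixels_per_degree is required for the Gabor family")
        wavelengths = [pixels_per_degree / f for f in gabor_frequencies_cpd]
    for lam in wavelengths:
        if lam < 2.0:
            raise ValueError(f"wavelength {lam} px below the 2 px Nyquist limit")
    channels = tuple(
        ChannelSpec(orientation_deg=theta, wavelength_px=lam,
                    sigma_ratio=sigma_ratio, angular_sigma_rad=angular_sigma_rad)
        for lam in sorted(wavelengths, reverse=True)
        for theta in orientations_deg
    )
    return FilterBank(channels=channels, family=family)
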