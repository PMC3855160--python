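"""Coarse-to-fine disparity selection from complex-cell response profiles.

For every channel the complex-cell energy is evaluated over an ordered set
of disparity hypotheses.  The stimulus disparity sits at a local *extremum*
(maximum or minimum) of the energy-versus-disparity profile at each pixel:
at the coarsest spatial frequency the extremum with the biggest response
magnitude is selected; at each finer frequency the extremum whose disparity
is closest to the previous (coarser) map is selected.  Estimates therefore
always belong to the hypothesis set (no interpolation).

Tie and degenerate-profile rules (all deterministic):

* equal-magnitude extrema (first scale) and equidistant extrema
  (refinement) resolve to the smaller ``|dx|``;
* plateaus (runs of exactly equal values) count as one extremum at the
  plateau centre, rounded toward smaller ``|dx|``;
* profile endpoints are never extrema;
* if a pixel has no interior extremum, the first scale falls back to the
  profile's global maximum and refinement keeps the previous value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import StereoPair, combined_transfer, complex_cell_energy
from .filterbank import (ChannelSpec, FilterBank, FrequencyGrid,
                         QuadratureFilter, compose_filter)


@dataclass(frozen=True)
class DisparityHypothesisSet:
    """Strictly increasing, uniformly stepped disparity hypotheses (pixels)."""

    values: np.ndarray = field(repr=False)
    step: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("hypothesis set must be a non-empty 1D array")
        if values.size > 1:
            diffs = np.diff(values)
            if np.any(diffs <= 0) or not np.allclose(diffs, self.step, atol=1e-9):
                raise ValueError("hypotheses must increase with a uniform step")
        object.__setattr__(self, "values", values)

    @classmethod
    def from_range(cls, lo: float, hi: float, step: float) -> "DisparityHypothesisSet":
        if step <= 0 or hi < lo:
            raise ValueError(f"invalid hypothesis range [{lo}, {hi}] step {step}")
        n = int(round((hi - lo) / step)) + 1
        return cls(values=lo + step * np.arange(n), step=step)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EnergyStack:
    """Complex-cell energy for every hypothesis of one channel: (K, H, W)."""

    energies: np.ndarray = field(repr=False)
    hypotheses: DisparityHypothesisSet
    channel: ChannelSpec


@dataclass(frozen=True)
class ChannelDisparityMap:
    """Per-pixel selected disparity and extremum response of one channel."""

    disparity: np.ndarray = field(repr=False)
    response: np.ndarray = field(repr=False)
    channel: ChannelSpec


# ---------------------------------------------------------------------------
# Energy stacks
# ---------------------------------------------------------------------------

def _upsample_factor(hypotheses: DisparityHypothesisSet, width: int) -> int | None:
    # smallest U such that every half-disparity shift is an integer number of
    # upsampled samples; None -> fall back to per-hypothesis phase ramps
    for u in (1, 2, 4, 8, 16):
        m = hypotheses.values * u / 2.0
        if np.all(np.abs(m - np.round(m)) < 1e-9):
            return u
    return None


def _upsample_columns(spectrum: np.ndarray, factor: int) -> np.ndarray:
    """Band-limited x-upsampling of the spatial signal whose 2D spectrum is given.

    Zero-pads the column frequencies (the Nyquist coefficient stays in the
    negative-frequency slot, matching ``fftfreq``'s -0.5 convention), so
    sampling the result reproduces the phase-ramp shift exactly.
    """
    if factor == 1:
        return np.fft.ifft2(spectrum)
    h, w = spectrum.shape
    half = w // 2
    padded = np.zeros((h, w * factor), dtype=complex)
    padded[:, :half] = spectrum[:, :half]
    padded[:, w * factor - (w - half):] = spectrum[:, half:]
    return np.fft.ifft2(padded) * factor


class _ShiftSampler:
    """Samples a complex response at integer-pixel grid shifted by m/factor px."""

    def __init__(self, spectrum: np.ndarray, factor: int):
        self.factor = factor
        upsampled = _upsample_columns(spectrum, factor)
        # residue views: view r holds samples at positions x*factor + r
        self.views = [np.ascontiguousarray(upsampled[:, r::factor])
                      for r in range(factor)]

    def at_shift(self, m: int) -> np.ndarray:
        """Values of the signal at positions x + m/factor for integer x."""
        # index x*factor + m = (x + q)*factor + r with r = m mod factor
        r = m % self.factor
        q = (m - r) // self.factor
        return np.roll(self.views[r], -q, axis=1)


def scan_disparities(pair: StereoPair, qf: QuadratureFilter, grid: FrequencyGrid,
                     hypotheses: DisparityHypothesisSet,
                     smooth_px: int = 0) -> EnergyStack:
    """Complex-cell energy of one channel for every disparity hypothesis.

    Equivalent to stacking :func:`~v1stereo.energy.complex_cell_energy` over
    the hypothesis set, but computed with two inverse FFTs per eye: the
    unshifted combined quadrature response is band-limit upsampled along x
    once, after which every (fractional) receptive-field shift is an integer
    resampling.  Falls back to per-hypothesis phase ramps when the step does
    not divide the upsampling grid.

    ``smooth_px`` > 0 applies an optional local-average (box) smoothing of
    that width to every energy map before extremum selection; off (0) by
    default — the model's standard form uses pointwise energies.
    """
    if len(hypotheses) == 0:
        raise ValueError("empty hypothesis set")
    if max(abs(hypotheses.values[0]), abs(hypotheses.values[-1])) / 2.0 >= grid.width / 4:
        raise ValueError("hypothesis range too wide for the image width")
    c = combined_transfer(qf)
    spec_l = np.fft.fft2(pair.left) * c
    spec_r = np.fft.fft2(pair.right) * c
    k = len(hypotheses)
    energies = np.empty((k, grid.height, grid.width))
    factor = _upsample_factor(hypotheses, grid.width)
    if factor is not None:
        # left RF at +d/2 -> response sampled at x - d/2; right at x + d/2
        samp_l = _ShiftSampler(spec_l, factor)
        samp_r = _ShiftSampler(spec_r, factor)
        for i, d in enumerate(hypotheses.values):
            m = int(round(d * factor / 2.0))
            z = samp_l.at_shift(-m) + samp_r.at_shift(+m)
            energies[i] = z.real ** 2 + z.imag ** 2
    else:
        for i, d in enumerate(hypotheses.values):
            energies[i] = complex_cell_energy(pair, qf, grid, d).energy
    if smooth_px > 1:
        from scipy.ndimage import uniform_filter
        energies = uniform_filter(energies, size=(1, smooth_px, smooth_px),
                                  mode="wrap")
    return EnergyStack(energies=energies, hypotheses=hypotheses, channel=qf.spec)


# ---------------------------------------------------------------------------
# Extremum detection on a single profile
# ---------------------------------------------------------------------------

def find_local_extrema(profile: np.ndarray,
                       disparities: np.ndarray | None = None
                       ) -> list[tuple[float, float, str]]:
    """Interior local extrema of an energy-versus-disparity profile.

    Returns ``(dx, value, kind)`` triples with ``kind`` in {"max", "min"}.
    Plateaus count once at their centre (rounded toward smaller ``|dx|``);
    runs touching an endpoint are excluded.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 3:
        raise ValueError("profile must be 1D with length >= 3")
    if disparities is None:
        disparities = np.arange(profile.size, dtype=float)
    else:
        disparities = np.asarray(disparities, dtype=float)
        if disparities.shape != profile.shape:
            raise ValueError("disparities must match the profile length")
    # compress runs of equal values
    runs: list[tuple[int, int]] = []  # (start, end) inclusive
    start = 0
    for i in range(1, profile.size):
        if profile[i] != profile[start]:
            runs.append((start, i - 1))
            start = i
    runs.append((start, profile.size - 1))
    out: list[tuple[float, float, str]] = []
    for j in range(1, len(runs) - 1):
        lo, hi = runs[j]
        value = profile[lo]
        prev_value = profile[runs[j - 1][1]]
        next_value = profile[runs[j + 1][0]]
        if value > prev_value and value > next_value:
            kind = "max"
        elif value < prev_value and value < next_value:
            kind = "min"
        else:
            continue
        mid = (lo + hi) / 2.0
        if mid == int(mid):
            idx = int(mid)
        else:  # even-length plateau: centre rounded toward smaller |dx|
            a, b = int(np.floor(mid)), int(np.ceil(mid))
            idx = a if abs(disparities[a]) <= abs(disparities[b]) else b
        out.append((float(disparities[idx]), float(value), kind))
    return out


# ---------------------------------------------------------------------------
# Per-pixel selection rules (scalar reference implementations)
# ---------------------------------------------------------------------------

def _select_first_pixel(profile: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    extrema = find_local_extrema(profile, disp)
    if not extrema:
        best = np.max(profile)
        cand = [d for d, v in zip(disp, profile) if v == best]
        d = min(cand, key=abs)
        return float(d), float(best)
    mag = max(abs(v) for _, v, _ in extrema)
    cand = [(d, v) for d, v, _ in extrema if abs(v) == mag]
    d, v = min(cand, key=lambda t: abs(t[0]))
    return float(d), float(v)


def _select_refine_pixel(profile: np.ndarray, disp: np.ndarray,
                         previous: float) -> tuple[float, float]:
    extrema = find_local_extrema(profile, disp)
    if not extrema:
        idx = int(np.argmin(np.abs(disp - previous)))
        return float(previous), float(profile[idx])
    dist = min(abs(d - previous) for d, _, _ in extrema)
    cand = [(d, v) for d, v, _ in extrema if abs(abs(d - previous) - dist) < 1e-9]
    d, v = min(cand, key=lambda t: abs(t[0]))
    return float(d), float(v)


# ---------------------------------------------------------------------------
# Vectorized selection over whole stacks
# ---------------------------------------------------------------------------

def _interior_extrema_masks(e: np.ndarray) -> np.ndarray:
    is_max = (e[1:-1] > e[:-2]) & (e[1:-1] > e[2:])
    is_min = (e[1:-1] < e[:-2]) & (e[1:-1] < e[2:])
    return is_max | is_min


def _plateau_pixels(e: np.ndarray) -> np.ndarray:
    # pixels whose profile has exactly-equal neighbours need the plateau-aware
    # scalar rule; strict comparisons handle everything else
    return np.any(e[1:] == e[:-1], axis=0)


def _argmin_with_tie(costs: np.ndarray, tiebreak: np.ndarray,
                     tol: float = 0.0) -> np.ndarray:
    """Index of min cost along axis 0; ties resolved by min tiebreak value."""
    cmin = costs.min(axis=0)
    with np.errstate(invalid="ignore"):  # inf - inf where a pixel has no candidate
        tied = np.abs(costs - cmin[None]) <= tol
    penal = np.where(tied, tiebreak[:, None, None], np.inf)
    return penal.argmin(axis=0)


def select_first_scale(stack: EnergyStack) -> ChannelDisparityMap:
    """Coarsest-scale selection: the extremum with the biggest |response|.

    Complex-cell energies are nonnegative, so the biggest-magnitude rule
    compares the raw values of maxima and minima alike (a deep profile's
    minimum can outrank a shallow maximum).  Pixels with no interior
    extremum fall back to the profile's global maximum.
    """
    e = stack.energies
    if e.shape[0] < 3:
        raise ValueError("need at least 3 hypotheses to locate extrema")
    disp = stack.hypotheses.values
    absd = np.abs(disp)
    cand = _interior_extrema_masks(e)
    has_ext = cand.any(axis=0)
    score = np.where(cand, np.abs(e[1:-1]), -np.inf)
    k_ext = _argmin_with_tie(-score, absd[1:-1]) + 1
    k_glob = _argmin_with_tie(-e, absd)
    k = np.where(has_ext, k_ext, k_glob)
    disparity = disp[k]
    response = np.take_along_axis(e, k[None], axis=0)[0]
    out = ChannelDisparityMap(disparity=disparity, response=response,
                              channel=stack.channel)
    return _patch_plateaus(out, stack, previous=None)


def select_refine(stack: EnergyStack, previous: ChannelDisparityMap | np.ndarray
                  ) -> ChannelDisparityMap:
    """Finer-scale selection: the extremum closest in disparity to the
    previous (coarser) map; pixels with no extremum keep the previous value."""
    e = stack.energies
    if e.shape[0] < 3:
        raise ValueError("need at least 3 hypotheses to locate extrema")
    prev = previous.disparity if isinstance(previous, ChannelDisparityMap) else np.asarray(previous, dtype=float)
    if prev.shape != e.shape[1:]:
        raise ValueError(f"previous map shape {prev.shape} does not match {e.shape[1:]}")
    disp = stack.hypotheses.values
    absd = np.abs(disp)
    cand = _interior_extrema_masks(e)
    has_ext = cand.any(axis=0)
    cost = np.where(cand, np.abs(disp[1:-1, None, None] - prev[None]), np.inf)
    k = _argmin_with_tie(cost, absd[1:-1], tol=1e-9) + 1
    disparity = np.where(has_ext, disp[k], prev)
    # response: the selected extremum, or the profile value at the carried
    # disparity when no extremum exists
    k_prev = np.clip(np.round((prev - disp[0]) / stack.hypotheses.step).astype(int),
                     0, len(disp) - 1)
    k_eff = np.where(has_ext, k, k_prev)
    response = np.take_along_axis(e, k_eff[None], axis=0)[0]
    out = ChannelDisparityMap(disparity=disparity, response=response,
                              channel=stack.channel)
    return _patch_plateaus(out, stack, previous=prev)


def _patch_plateaus(result: ChannelDisparityMap, stack: EnergyStack,
                    previous: np.ndarray | None) -> ChannelDisparityMap:
    # exact value ties are measure-zero for real energies; when they do occur
    # (degenerate synthetic inputs) re-run the plateau-aware scalar rule on
    # the affected pixels only
    mask = _plateau_pixels(stack.energies)
    if not mask.any():
        return result
    disparity = result.disparity.copy()
    response = result.response.copy()
    disp = stack.hypotheses.values
    for y, x in zip(*np.nonzero(mask)):
        profile = stack.energies[:, y, x]
        if previous is None:
            d, v = _select_first_pixel(profile, disp)
        else:
            d, v = _select_refine_pixel(profile, disp, float(previous[y, x]))
        disparity[y, x] = d
        response[y, x] = v
    return ChannelDisparityMap(disparity=disparity, response=response,
                               channel=result.channel)


# ---------------------------------------------------------------------------
# Full coarse-to-fine pass
# ---------------------------------------------------------------------------

def run_coarse_to_fine(pair: StereoPair, bank: FilterBank, grid: FrequencyGrid,
                       hypotheses: DisparityHypothesisSet,
                       rf_window: tuple[int, int] | None = None,
                       smooth_px: int = 0) -> list[ChannelDisparityMap]:
    """Chain the selection rules over scales, independently per orientation.

    Returns one map per (orientation, scale) channel in the bank's own
    (coarse-to-fine) order — for 6 orientations x 4 scales, 24 maps.  Within
    an orientation, the coarsest scale uses :func:`select_first_scale` and
    every finer scale refines against the previous scale's map.

    Orientations 180 degrees apart have conjugate complex responses and thus
    exactly identical energies and maps; each mirror pair is computed once.
    """
    from .filterbank import truncate_spatial_support

    wavelengths = bank.wavelengths_px  # coarsest first
    orientations = bank.orientations_deg
    chains: dict[float, dict[float, ChannelDisparityMap]] = {}
    for theta in orientations:
        mirror = next((o for o in chains
                       if abs(((theta - o) % 360.0) - 180.0) < 1e-9), None)
        if mirror is not None:
            chains[theta] = {
                lam: ChannelDisparityMap(
                    disparity=m.disparity, response=m.response,
                    channel=ChannelSpec(
                        orientation_deg=theta, wavelength_px=lam,
                        sigma_ratio=m.channel.sigma_ratio,
                        angular_sigma_rad=m.channel.angular_sigma_rad))
                for lam, m in chains[mirror].items()}
            continue
        chain: dict[float, ChannelDisparityMap] = {}
        previous: ChannelDisparityMap | None = None
        for lam in wavelengths:
            spec = next(c for c in bank.channels
                        if c.wavelength_px == lam and c.orientation_deg == theta)
            qf = compose_filter(grid, spec, bank.family)
            if rf_window is not None:
                qf = truncate_spatial_support(qf, grid, rf_window)
            stack = scan_disparities(pair, qf, grid, hypotheses,
                                     smooth_px=smooth_px)
            previous = (select_first_scale(stack) if previous is None
                        else select_refine(stack, previous))
            chain[lam] = previous
        chains[theta] = chain
    return [chains[c.orientation_deg][c.wavelength_px] for c in bank.channels]
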