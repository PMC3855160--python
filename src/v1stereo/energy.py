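"""Binocular simple-cell and complex-cell energy responses.

A binocular simple cell sums the filtered left- and right-eye images; its
push-pull (ON/OFF) pair squares the half-wave rectified sum and its inverse,
which together restore the full squared signal (``ON^2 + OFF^2 = s^2``).
A complex cell adds the even- and odd-phase push-pull pairs, producing a
phase-invariant, disparity-tuned "energy".  Disparity hypotheses are applied
as positional shifts of the two eyes' receptive fields: the left filter
centre moves by +dx/2 and the right by -dx/2, implemented as frequency-domain
phase ramps so fractional shifts are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filterbank import ChannelSpec, FrequencyGrid, QuadratureFilter


@dataclass(frozen=True)
class StereoPair:
    """A left/right pair of same-shape 2D luminance images."""

    left: np.ndarray = field(repr=False)
    right: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        if left.ndim != 2 or left.shape != right.shape:
            raise ValueError(
                f"left/right must be same-shape 2D images, got {left.shape} and {right.shape}")
        if not (np.isfinite(left).all() and np.isfinite(right).all()):
            raise ValueError("stereo pair contains non-finite values")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    @property
    def shape(self) -> tuple[int, int]:
        return self.left.shape


@dataclass(frozen=True)
class MonocularResponse:
    """Even/odd filtered responses of one eye for one channel."""

    even_part: np.ndarray = field(repr=False)
    odd_part: np.ndarray = field(repr=False)
    channel: ChannelSpec
    eye: str
    shift_px: float = 0.0


@dataclass(frozen=True)
class EnergyMap:
    """Complex-cell energy per pixel for one disparity hypothesis."""

    energy: np.ndarray = field(repr=False)
    channel: ChannelSpec
    disparity_px: float


def preprocess(image: np.ndarray) -> np.ndarray:
    """Subtract the mean luminance, attenuating the DC component.

    Applied to both eyes' images before filtering, for both filter families
    (for the log-Gabor family it is redundant — the filters have no DC —
    but keeps the comparison symmetric).  Idempotent.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2D image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    return image - image.mean()


def shift_transfer(weights: np.ndarray, grid: FrequencyGrid,
                   delta_px: float) -> np.ndarray:
    """Phase-ramp a transfer function so its kernel centre moves by +delta_px.

    ``h(x - d) <-> H(u) * exp(-2 pi i u d)`` along the horizontal axis; the
    shift is exact for fractional ``delta_px``.  Shifts compose additively.
    """
    if abs(delta_px) >= grid.width / 4:
        raise ValueError(
            f"|shift| {abs(delta_px)} px exceeds a quarter of the image width")
    if delta_px == 0.0:
        return weights
    ramp = np.exp(-2j * np.pi * grid.ux * delta_px)
    return weights * ramp[None, :]


def apply_positional_shift(obj, grid: FrequencyGrid, delta_px: float):
    """Shift a transfer array or a whole QuadratureFilter by +delta_px."""
    if isinstance(obj, QuadratureFilter):
        return QuadratureFilter(
            even=shift_transfer(obj.even, grid, delta_px),
            odd=shift_transfer(obj.odd, grid, delta_px),
            family=obj.family, spec=obj.spec, shape=obj.shape)
    return shift_transfer(np.asarray(obj), grid, delta_px)


def filter_image(image: np.ndarray, qf: QuadratureFilter,
                 eye: str = "left", shift_px: float = 0.0,
                 grid: FrequencyGrid | None = None) -> MonocularResponse:
    """Apply a quadrature filter to an image in the frequency domain.

    The filters are one-sided in frequency; the real simple-cell signals are
    the real parts of the complex inverse transforms (equivalent to applying
    the Hermitian-symmetrized even transfer and the anti-symmetrized odd
    transfer).
    """
    image = np.asarray(image, dtype=float)
    if image.shape != qf.shape:
        raise ValueError(f"image shape {image.shape} does not match filter {qf.shape}")
    even_w, odd_w = qf.even, qf.odd
    if shift_px != 0.0:
        if grid is None:
            raise ValueError("grid is required to apply a positional shift")
        even_w = shift_transfer(even_w, grid, shift_px)
        odd_w = shift_transfer(odd_w, grid, shift_px)
    spectrum = np.fft.fft2(image)
    even_part = np.fft.ifft2(spectrum * even_w).real
    odd_part = np.fft.ifft2(spectrum * odd_w).real
    return MonocularResponse(even_part=even_part, odd_part=odd_part,
                             channel=qf.spec, eye=eye, shift_px=shift_px)


def simple_cell_pair(left: MonocularResponse, right: MonocularResponse,
                     phase: str) -> np.ndarray:
    """Response of a push-pull (ON/OFF) pair of binocular simple cells.

    The binocular sum ``s = left + right`` is half-wave rectified into ON
    (= max(s, 0)) and OFF (= max(-s, 0)) cells, each squared; their sum
    equals ``s**2`` exactly, which is why the pair removes the rectification.
    """
    if phase not in ("even", "odd"):
        raise ValueError(f"phase must be 'even' or 'odd', got {phase!r}")
    if left.channel != right.channel:
        raise ValueError("left/right responses come from different channels")
    lpart = left.even_part if phase == "even" else left.odd_part
    rpart = right.even_part if phase == "even" else right.odd_part
    if lpart.shape != rpart.shape:
        raise ValueError("left/right response dimensions differ")
    s = lpart + rpart
    on = np.maximum(s, 0.0)
    off = np.maximum(-s, 0.0)
    return on ** 2 + off ** 2


def complex_cell_energy(pair: StereoPair, qf: QuadratureFilter,
                        grid: FrequencyGrid, disparity_px: float) -> EnergyMap:
    """Complex-cell energy for one disparity hypothesis.

    The left receptive field is displaced by +disparity/2 and the right by
    -disparity/2; the energy is the sum of the even and odd push-pull pair
    responses.  Images are expected mean-subtracted (see :func:`preprocess`).

    The shift is applied to the combined quadrature transfer (one phase ramp
    on the complex response), which at zero or integer shift is identical to
    shifting the even and odd transfers separately and keeps fractional
    shifts self-consistent at the Nyquist column.
    """
    half = disparity_px / 2.0
    c = combined_transfer(qf)
    z_l = np.fft.ifft2(np.fft.fft2(pair.left) * shift_transfer(c, grid, +half))
    z_r = np.fft.ifft2(np.fft.fft2(pair.right) * shift_transfer(c, grid, -half))
    resp_l = MonocularResponse(even_part=z_l.real, odd_part=z_l.imag,
                               channel=qf.spec, eye="left", shift_px=+half)
    resp_r = MonocularResponse(even_part=z_r.real, odd_part=z_r.imag,
                               channel=qf.spec, eye="right", shift_px=-half)
    energy = (simple_cell_pair(resp_l, resp_r, "even")
              + simple_cell_pair(resp_l, resp_r, "odd"))
    return EnergyMap(energy=energy, channel=qf.spec, disparity_px=disparity_px)


# ---------------------------------------------------------------------------
# Fast combined-response machinery (used by the disparity scan)
# ---------------------------------------------------------------------------

def _negate_frequencies(weights: np.ndarray) -> np.ndarray:
    # W(-u, -v) on the unshifted DFT layout: reverse both axes, roll by one
    return np.roll(weights[::-1, ::-1], 1, axis=(0, 1))


def hermitize(weights: np.ndarray) -> np.ndarray:
    """Hermitian-symmetrize a transfer: ``(W(u) + conj(W(-u))) / 2``.

    Applying the symmetrized transfer to a real image's spectrum gives the
    same result as taking the real part after applying ``W`` itself.
    """
    return 0.5 * (weights + np.conj(_negate_frequencies(weights)))


def combined_transfer(qf: QuadratureFilter) -> np.ndarray:
    """Single complex transfer whose response carries both quadrature parts.

    ``C = hermitize(even) + i * hermitize(odd)``: for a real input image,
    ``z = ifft2(fft2(img) * C)`` has ``Re z`` equal to the even simple-cell
    signal and ``Im z`` equal to the odd one, so one inverse FFT yields the
    full quadrature response.
    """
    return hermitize(qf.even) + 1j * hermitize(qf.odd)


def complex_response(image: np.ndarray, qf: QuadratureFilter) -> np.ndarray:
    """Combined complex response: real part = even, imaginary part = odd."""
    return np.fft.ifft2(np.fft.fft2(np.asarray(image, dtype=float))
                        * combined_transfer(qf))
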