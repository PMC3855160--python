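# Methods

`v1stereo` implements a position-shift binocular energy model of disparity
estimation: the stimulus disparity is decoded from the responses of model
V1 complex cells whose left- and right-eye receptive fields (RFs) are
identical in shape but displaced horizontally.  This note documents the
model, its parameters, the synthetic benchmark, and the numerical and
design choices that the code embodies.

## Model

### Filter bank

Simple-cell RFs are band-pass filters built directly in the discrete
Fourier domain on the unshifted layout (DC at bin (0, 0)), in normalized
frequency units (cycles/pixel, Nyquist 0.5).  Converting bin coordinates to
polar form (ρ = √(u²+v²), φ = atan2(v, u), anticlockwise), each channel is
the product of two separable terms:

* an angular Gaussian `exp(−Δθ²/(2σ_θ²))`, where Δθ is the wrapped angular
  distance to the channel orientation (computed through the sine/cosine
  difference in the rotated frame, so it behaves correctly at ±π);
* a radial envelope.  For the **log-Gabor** family this is a Gaussian on a
  logarithmic frequency axis, `exp(−ln²(ρ/f₀) / (2 ln²(σ_r/f₀)))`, with the
  DC bin set to exactly zero — the log-Gabor has no DC component at any
  bandwidth and is symmetric on a log axis, matching measured V1 tuning
  curves.  For the baseline **Gabor** family the radial term is a Gaussian
  on a *linear* frequency axis whose half-amplitude width matches the
  log-Gabor's octave bandwidth; its DC weight `exp(−f₀²/(2σ_r²))` is
  strictly positive, the classical Gabor defect that grows with bandwidth.

The quadrature (odd-phase) partner of each even filter is its Hilbert
transform along the channel orientation, `odd = i·sign(u·cosθ + v·sinθ)·even`,
which has identical amplitude spectrum and exactly zero DC.  Complex cells
built from Hilbert pairs are phase invariant, which sine/cosine Gabor pairs
with unequal DC are not.

Two discrete-grid subtleties: bins on which the orientation projection is
exactly zero (DC and, for axis-aligned channels, the perpendicular
frequency line) have no well-defined Hilbert sign and are zeroed in both
partners; and the Nyquist row/column of an even-sized DFT are their own
negative frequencies, so one-sided filters are ill-defined there — all
filters are band-limited to the open interval (−0.5, 0.5).  The second
choice also makes channels 180° apart exact conjugate mirrors, which the
pipeline exploits by computing each mirror pair once.

The Gabor baseline is deliberately built in the same polar-separable form
as the log-Gabor bank (same angular envelope, same quadrature construction)
rather than as a Cartesian sine/cosine pair: the two families then differ
*only* in the radial axis (logarithmic vs linear), which is precisely the
comparison of interest.

### Binocular energy

Images are mean-subtracted before filtering (attenuating the DC component;
redundant for log-Gabor channels, material for the Gabor baseline).  For a
disparity hypothesis Δx the left RF is displaced by +Δx/2 and the right by
−Δx/2, as frequency-domain phase ramps, so fractional shifts are exact.  A
binocular simple cell sums the two eyes' filtered signals, `s = L + R`; its
push-pull (ON/OFF) pair contributes `max(s,0)² + max(−s,0)² = s²`, removing
the half-wave rectification.  The complex cell adds the even- and odd-phase
pairs:

    E(x, y; Δx) = s_even² + s_odd²

which is nonnegative, phase invariant, and — for identical left/right
images — an even (tuned-excitatory) function of Δx.  No spatial pooling of
the energy is applied; an optional local-average smoothing exists behind a
flag and is off by default.

### Coarse-to-fine selection

The energy is evaluated on a uniform hypothesis grid (default −6..+6 px;
step 1.0 px for the square stimulus, 0.25 px otherwise).  Per pixel and per
channel, candidate disparities are the interior local extrema (maxima or
minima) of the energy-vs-Δx profile.  At the coarsest spatial frequency the
extremum with the biggest response magnitude is selected; at each finer
frequency the extremum whose disparity is closest to the previous
(coarser) map of the same orientation.  Estimates always belong to the
hypothesis grid (no interpolation).  Deterministic tie rules: equal
magnitudes or equal distances resolve to the smaller |Δx|; exact-value
plateaus count once at their centre (rounded toward smaller |Δx|);
endpoints are never extrema; a pixel with no interior extremum falls back
to the profile's global maximum (first scale) or carries the previous value
(refinement).

### Pooling

The 24 per-(orientation, scale) maps are pooled per pixel by robust
averaging: iteratively remove the channel value farthest from the current
mean until ⌈n/2⌉ survive, then average.  Distance ties remove the
lowest-indexed channel.  The pooled value is always inside the surviving
values' range, and 13 exactly agreeing channels out of 24 determine the
output regardless of the other 11.  A per-pixel median is available as an
optional baseline.

## Synthetic benchmark

Stereograms are 200×200 binary random-dot fields (density 0.5, 1-px dots,
two-level contrast), warped so that right-image content is displaced by
+d(x, y): `right(x) = left(x − d)` with linear interpolation for fractional
d; samples falling outside the field are refilled with fresh seeded dots
(no wraparound).  Three disparity profiles: a centred 100×100 square at
+5 px over a −1 px surround; a 160×160 region ramping −5..+5 px across
columns over a zero surround; and 5 px times a centred 2-D Gabor surface
(0.4 cycles/degree at 40 px/degree ≈ 100 px wavelength, σ = 40 px, phase 0 —
chosen once as a representative smooth corrugation).  Everything is
reproducible from (kind, seed, parameters).

What the generator does *not* emulate: occlusion/uncovering geometry (the
refill is uncorrelated dots rather than a half-occluded region), vertical
disparity, photometric differences between eyes, and natural-image (1/f)
statistics.  Passing the synthetic suite therefore demonstrates correct
disparity decoding under ideal binocular geometry, not robustness to
real-world imaging effects.

Evaluation uses the bad-pixel percentage B (share of valid pixels with
|error| strictly greater than 0.25 px) and the RMS error R, over an
interior region excluding a 13 px border (the largest filter wavelength,
12.288 px, rounded up; circular filtering contaminates the rim).
Real-world stereo pairs use threshold 1 px and an 18 px border, with a
negative hypothesis range (e.g. 0..−19 px, step 0.5) matched to the scene's
ground-truth range.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| orientations (log-Gabor) | 30, 60, 90, 210, 240, 270 | deg | angular positions of the frequency lobes; 210/240/270 are conjugate mirrors of 30/60/90 and yield identical energies |
| orientations (Gabor) | 30, 60, 90, 120, 150, 180 | deg | baseline set |
| scales | 4; λ = 3·1.6^k px (3, 4.8, 7.68, 12.288) | px | coarse-to-fine ladder |
| σ_r/f₀ | 0.65 | — | ≈1.5 octave half-amplitude bandwidth, the complex-cell population average |
| σ_θ | 0.25 | rad | calibrated on the synthetic benchmark (see below) |
| Gabor frequencies | 0.5, 1, 2, 4 c/deg at 12 px/deg | — | 12 px/deg maps 4 c/deg exactly onto the 3 px finest log-Gabor wavelength, making the two families' finest scales coincide |
| hypothesis range | −6..+6 | px | the stimulus range (±5 px) plus one step of margin, so stimulus extremes remain interior extrema; mirrors the practice of matching the search range to the ground-truth range |
| hypothesis step | 1.0 (square), 0.25 (ramp/surface) | px | benchmark protocol |
| dot density / size | 0.5 / 1 px | — | generator convention |
| border / threshold | 13 px / 0.25 px (synthetic); 18 px / 1 px (real-world) | — | see above |

σ_θ controls the trade-off at the heart of this model: narrow angular
tuning (small σ_θ) makes RFs long, which regularises the pointwise energy
(the dominant error source, see Limitations) but blurs depth boundaries.
It was calibrated once by scanning 0.15–0.65 rad against the benchmark's
mean B and R and fixed at 0.25 rad for all results.

## Numerical choices

* Filters multiply `numpy.fft.fft2` spectra directly; simple-cell signals
  are the real parts of the complex inverse transforms (equivalently,
  Hermitian-symmetrized transfers).  One complex inverse FFT per eye and
  channel carries both quadrature parts (`C = herm(even) + i·herm(odd)`).
* The disparity scan upsamples the combined complex response along x by
  zero-padding its spectrum (Nyquist coefficient kept in the
  negative-frequency slot), after which every hypothesis shift is an
  integer resampling; this is bit-for-bit the phase-ramp shift and is
  tested against the direct per-hypothesis path.
* Circular (wrap-around) convolution is accepted and masked by the
  evaluation border rather than padded away.
* Vectorized extremum selection uses strict inequalities; profiles
  containing exact value ties anywhere are re-run per pixel through the
  plateau-aware scalar rule, so degenerate inputs follow the documented
  tie-breaking exactly.
* Refinement distance ties use a 1e−9 tolerance (grid arithmetic);
  magnitude ties at the first scale are exact comparisons.

## Known limitations

* **Pointwise energy floor.**  With 1-px binary dots and no spatial
  pooling, the filtered analytic envelope has frequent near-zeros; at such
  pixels the energy-vs-Δx profile is uninformative and every channel's
  estimate is unreliable.  This places a floor of roughly 5–15 % bad pixels
  (threshold 0.25 px) on uniform-disparity stimuli that no setting of σ_θ
  removes, and it is the dominant contribution to the benchmark's B away
  from depth edges.  Accuracy targets for this architecture that fall
  substantially below this floor require additional integration (larger
  dots, lower density, or spatial pooling of the energy) not modelled
  here.
* **Depth-edge blur.**  RFs tens of pixels long cannot localise the ±6 px
  disparity jumps of the square and ramp stimuli better than a band of
  several pixels around each edge; errors concentrate there.
* The 180°-mirrored orientation channels double the channel count without
  adding information (they are exact duplicates); they are kept for
  protocol fidelity.
* The hypothesis-set closure (no sub-step interpolation) bounds the ramp
  and surface accuracy at the 0.25 px threshold; pooling across channels
  recovers some sub-step resolution by averaging quantized estimates.
* Gabor-surface truth parameters and several baseline conventions
  (pixels/degree, dot statistics) are package choices; results are always
  reported together with the full serialized configuration.
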