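# Methods

This note documents the models, estimators and numerical choices behind
the package, what the synthetic generators do and do not emulate, and the
known limitations of each readout.

## Noise model

Quantum noise in fluoroscopy is Poisson distributed in the detected
photon count; the digitized pixel value is (approximately) the count
scaled by the detector gain plus additive Gaussian electronics noise.
Two consequences are used throughout:

1. the expected value–variance relationship is affine,
   `σ²(h) = A·h + B`, with `A` (a.u.) the gain-determined slope and `B`
   (a.u.²) the electronics variance;
2. for counts above ~10 the Poisson branch is well approximated by a
   Gaussian with matching variance, so a noisy pixel can be modelled as
   `g = h + N(0, σ²(h))`.

`sample_noisy` offers both forms: `poisson_gaussian` draws
`A·Poisson(h/A) + N(0, B)` (the physical mixture; requires `A > 0`,
`B ≥ 0`), `gaussian_approx` draws the matched-moment Gaussian (valid for
`h/A ≳ 10`, and the only option when a fitted `B` is negative). Both
have mean `h` and variance `A·h + B`.

Fitted `B` values on real data can be slightly negative; the variance is
therefore floored at `ε = 1e-12 a.u.²` so that thresholds remain defined
at very low gray levels, and construction of `NoiseParams` warns when
the affine law goes negative anywhere in the declared level range. The
floor is far below any realistic variance and never affects mid-range
behaviour. The degenerate pair `A = B = 0` is accepted as the exact
zero-noise limit (used by the phantom generators for clean/ideal
output).

Reference parameter sets `FLUORO_TEMPORAL` (A = 43.90e-4 a.u.,
B = −0.99e-4 a.u.²) and `FLUORO_SPATIAL` (A = 37.91e-4, B = 0.05e-4)
reproduce the values estimated on a GE 9900 Elite C-arm sequence
(57 kVp, 1 mA, 25 fps, 16-bit data normalized to [0, 1] a.u.) by the
temporal per-pixel method and by a per-frame spatial method,
respectively. The two disagree on `B`'s sign; both are exposed and the
demo configurations default to the temporal estimates (with `B` clamped
to 0 wherever the Poisson mixture sampler needs `B ≥ 0`).

## Generalized Anscombe transform

`gat_forward` applies `f(z) = (2/A)·√(A·z + (3/8)A² + B − A·pedestal)`,
which maps the mixed noise to approximately unit-variance Gaussian for
`h/A ≳ 10`; the argument is clamped at zero before the square root and
the clamp count is recorded in the output metadata (`gat_clamped`) and
logged. `gat_inverse_algebraic` is the exact functional inverse on the
non-clamped domain (round-trip error is at the 1e-16 level). The
exact-unbiased inverse of the literature is deliberately not provided:
the algebraic inverse is the variant used in the fluoroscopy
post-filtering workflow this package supports, and the small low-count
bias it carries is irrelevant to the filter itself (NVCA operates on raw
values, not on transformed ones).

## Temporal noise estimation

On a motionless sequence, each pixel's frames are independent draws
around its clean level, so the per-pixel temporal mean `m` and unbiased
variance `v` (ddof = 1) sample the EV–variance line. `estimate_temporal`
regresses `v` on `m` by ordinary unweighted least squares over all
retained pixels — the simplest faithful estimator; a variance-weighted
or binned variant would be more efficient, and an equal-count binning
option (`n_bins`) is provided but is not the default. `R²` is the plain
coefficient of determination of that regression. Degenerate inputs are
rejected with actionable messages: fewer than 2 frames, all means at a
single level (the line is unidentifiable; use a multi-level phantom), or
all variances zero (noiseless input); both degeneracy checks use small
relative tolerances rather than exact zero so that floating-point dust
does not slip through. Optional clipping exclusion drops pixels whose
mean lies within `clip_margin` of the global extremes; the default is no
exclusion (margin 0), since the synthetic phantoms never clip.

Autocovariances are reported unnormalized (a.u.²), with a normalized
(lag-0 = 1) view available. The spatial estimate subtracts the ROI mean
per frame, computes the biased 2-D autocovariance (divisor = ROI pixel
count, which guarantees the lag-0 value dominates), averages over
frames, and takes the radial profile by averaging entries with the same
integer-rounded Euclidean radius. The temporal estimate is the biased
per-pixel 1-D autocovariance averaged over ROI pixels, so lag 0 equals
the ROI-averaged temporal variance.

## The NVCA filter

For each pixel, neighbours in an `N × N × K` mask are admitted when
their absolute difference from the centre is at most
`T = F·σ(I(x, y, t))`, and the output is the mean of the admitted
values. Numerical/boundary choices:

* **Causal window.** The temporal extent covers the current frame and
  `K − 1` past frames only; a centred variant is intentionally not
  provided, matching real-time streaming operation. `K = 1` gives a
  purely spatial filter.
* **Truncation, no padding.** Out-of-bounds neighbours (spatial borders,
  the first `K − 1` frames) simply get `C = 0`; the denominator adapts,
  so no data is invented.
* **Threshold argument.** `T` is evaluated at the centre pixel's
  *observed* value, the available proxy for its expected value; there is
  no iterative refinement. This makes the filter a pure two-pass-free
  point operation, at the cost of a small bias near edges (see
  Limitations).
* **Exact flats.** The admitted mean is accumulated in centred form,
  `centre + Σ(neighbour − centre)/count`, so constant regions map to
  themselves exactly in floating point and `F = 0` is an exact identity
  on distinct-valued data.
* **LUT variant.** `build_threshold_lut` tabulates `T` on a uniform
  grid (default 2¹⁶ levels over the declared range, emulating 16-bit
  hardware); lookups map to the nearest grid level with ties rounding
  half up. On data quantized to the grid, the LUT path is bit-identical
  to direct evaluation.
* **Mask geometry.** The spatial extent is always square `N × N` with
  `N` odd (symmetry about the centre); only `K` varies independently.

The moving-average baseline is the same geometry and border handling
with every in-bounds neighbour admitted (the `F → ∞` limit, which the
implementation reproduces exactly).

Every output pixel is a convex combination of admitted inputs, so the
filter can never exceed the input min/max; causality is verified by
mutating future frames; and the vectorized implementation is checked
bit-for-bit against an independent per-pixel brute-force transliteration
of the rule on over a hundred random small instances.

## Synthetic phantoms

**Step phantom** — concentric nested squares over a background, constant
in time, emulating the projected image of a stack of square attenuating
sheets (relative side lengths default to the 30/26/22/18/14/10/6
proportions of such a stack, with the largest square spanning 90% of the
smaller frame dimension). Default gray levels are 8 values geometrically
spaced from 0.8 (background) down to 0.1 a.u. — each added sheet
attenuates by a constant factor — and the default size is 328 × 333 px
by 712 frames, the scale of a real noise-characterization sequence.
Every pixel belongs to exactly one flat region and the returned
`region_map` labels them for ROI selection. Two optional dark "screw"
discs can be added as decorations (labelled −1, excluded from region
statistics).

**Moving-insert phantom** — motionless discs of several sizes and
contrasts plus a darker rectangle translating left to right at an
integer number of pixels per frame. The insert level is
`0.46 × background` exactly (the insert is radiopaque; contrast defined
as the percent ratio of insert mean to background mean), background
0.5 a.u., frame 256 × 256, insert 60 × 80 px by default. Only integer
speeds are accepted: fractional motion would anti-alias the edges and
break the ideal-edge guarantee on which the FWHM ground truth rests.
The generator returns a per-frame ROI centred on the insert's leading
vertical edge (corner rows excluded, ≥ 10 profile rows), so profile
extraction is perfectly registered without tracking.

Noise for both phantoms defaults to the Poisson-dominant choice
(`A = 43.90e-4`, `B = 0`) — the level estimated on real fluoroscopy,
with the electronics term dropped because the mixture sampler requires
`B ≥ 0` and the fitted `B` is two orders of magnitude smaller than
`A·h` at mid-gray.

What the phantoms do **not** emulate: the imaging system's point-spread
function (all clean edges are ideal single-pixel transitions, whereas
real edges carry intrinsic blur), detector lag (frames are temporally
independent), scatter, beam hardening, spatial noise correlation, and
value clipping. Consequences for interpreting results are noted under
Limitations.

## Image-quality metrics

**Edge FWHM.** Profiles across an edge are fitted with
`offset + amplitude·ψ(x; c, d)`, `ψ(x) = 0.5·(1 − erf((x − c)/(√2·d)))`
— the ideal edge blurred by a Gaussian line-spread function of standard
deviation `d` — and the FWHM is reported as `2.355·d` (2√(2 ln 2)),
never as a numerical half-maximum crossing. The two affine parameters
extend the unit-amplitude model because real profiles are not
normalized. Initialization: `c` at the maximum-|gradient| sample,
`d = 1 px`, offset/amplitude from the plateau medians; `d` is bounded
below by 1e-6 px. Non-convergent or poor fits (`R²` below a
configurable floor, default 0.5) are returned flagged with diagnostics
rather than raised, and `fwhm_over_profiles` excludes and counts them
while averaging the per-profile FWHM over `n_profiles` consecutive
1-px-spaced profiles (mean ± standard deviation). A flat profile is
rejected outright. Noiseless synthetic erf edges are recovered to
≤ 1e-6 px over `d ∈ [0.5, 5]`.

**CNR.** `√2·(μ_A − μ_B)/√(σ_A² + σ_B²)` with sample standard
deviations (ddof = 1) over two disjoint ROIs of ≥ 4 px each; sequences
get per-frame values plus their mean. Zero pooled variance is an error
(CNR undefined).

**FSIM.** The published feature-similarity index: phase-congruency maps
from a 4-scale, 4-orientation log-Gabor bank (minimum wavelength 6,
scale multiplier 2, σ_onf 0.55, Rayleigh noise compensation with k = 2)
and Scharr gradient magnitudes, combined with constants T1 = 0.85,
T2 = 160 and pooled with the pointwise-max phase congruency as weight.
Both inputs are first *jointly* rescaled to a 0–255 dynamic range (so a
common affine gray transform cancels exactly) and downsampled by
`round(min(shape)/256)` after box smoothing. All parameters are recorded
in the result. For motionless sequences the reference image is the
pixel-wise temporal mean of the raw frames; note this reference retains
residual noise of variance `σ²/n_frames`, so FSIM values against it are
slightly pessimistic — the frame count is reported alongside for that
reason.

## Problem sizes used by the test suite and the acceptance script

The suite exercises the full 712-frame, 328 × 333 px step sequence once
(for the EV–variance regression quality check) and otherwise uses
reduced geometries chosen to keep every statistic comfortably
significant: 96–160 px frames, 10–300 frames, 10–20 seeds for
trend/recovery statistics. The acceptance script runs the three
moving-insert sequences at 40 frames each with the evaluation frame late
enough (index 30) that the temporal window is in steady state.
Trend-vs-threshold experiments use a dedicated two-step phantom with
wide flat regions (the default nested geometry leaves only ~9 px between
consecutive edges, too narrow for the ~37-sample profiles the erf fit
needs) and an edge contrast of ~3 local noise standard deviations — the
regime in which the threshold factor actually sweeps cross-edge
admission from rare (F = 1) to common (F = 3).

## Limitations and known behaviours

* **Sigma-filter bias.** Because admission is conditioned on the
  centre's observed value, the filtered value stays correlated with the
  centre's own noise draw; residual noise at F = 1 is a substantial
  fraction of the input noise, and near edges the output is biased a few
  mσ toward the centre's side. This is inherent to the conditioned
  average, not an implementation artifact.
* **FWHM noise floor on ideal edges.** Fitting an erf to an essentially
  ideal noisy step yields a small positive spread (`d` is bounded below
  by zero, so noise cannot average out), roughly proportional to the
  residual noise-to-contrast ratio. Two consequences documented here
  because they shape test design: (i) NVCA FWHM values on the
  moving-insert phantom are sub-pixel noise-floor readings, so
  MA-to-NVCA FWHM *ratios* fluctuate strongly between seeds even though
  the separation is always large; (ii) on ideal-edge synthetic data the
  FWHM-vs-threshold-factor curve is U-shaped — the floor falls from
  F = 1 to F = 2 as the filter averages more neighbours, before
  cross-edge admission blur takes over and raises it from F = 2 to
  F = 3. On real edges carrying system PSF blur the intrinsic width
  dominates the floor and the curve rises monotonically; passing the
  synthetic trend tests therefore shows the admission-blur mechanism
  (F = 2 → 3) and the CNR trade-off, not the full monotone resolution
  curve seen on real data.
* **Thresholding quality depends on (A, B).** The filter is only as
  good as the noise characterization; details whose contrast lies below
  the local noise level are averaged away by design.
* **No motion compensation.** NVCA preserves moving edges by exclusion,
  not by tracking; it does not reduce noise across frames for fast-moving
  content (the admitted temporal neighbours are simply fewer there).
* **FSIM reference bias** as noted above for time-average references on
  short sequences.
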