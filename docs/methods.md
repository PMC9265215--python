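# Methods

## Registration model

The correction model is rigid translation only. In head-mounted one-photon
imaging the lens is in contact with the tissue and moves with it, so
rotations, shears and the raster-scan warping of two-photon systems are
rare; what remains is frame-wide (dx, dy) shake. One sign convention is
used everywhere: a shift (dx, dy) means scene content moved dx columns
right and dy rows down relative to the reference, registration reports
that same quantity, and correction applies (−dx, −dy) with bilinear
interpolation, zero-filling exposed borders.

### High-pass filtering

The kernel is an unnormalized Gaussian of standard deviation `sigma` on a
square grid of side `ceil(size_factor × neuron_diameter)` (rounded up to
odd), minus its own spatial mean, so the coefficients sum to zero.
Defaults: `neuron_diameter = 10` px (the typical miniscope soma),
`size_factor = 3`, `sigma = neuron_diameter / 2`. The sigma default
deserves a note: "the width of a neuron" can be read as diameter or
radius. With `sigma` equal to the full diameter and a side of only three
diameters, the mean-subtracted kernel is nearly flat and filters poorly;
with radius-scale sigma the positive lobe matches the soma, which is the
common choice in one-photon preprocessing. Both readings are available
via `filter.sigma`; the radius is the default. Convolution uses reflection
padding so the frame border does not generate a spurious step response.

### NCC and why it is computed via FFTs

For each candidate integer shift the similarity is the Pearson correlation
restricted to the overlap region of the two images. All five overlap sums
it needs (cross product, two sums, two sums of squares) plus the overlap
pixel count are cross-correlations of the images, their squares, and an
all-ones mask, so the whole map over a (2·max_shift+1)² window costs a
handful of FFTs instead of a per-shift loop. Numerical choices:

- images are zero-padded to `next_fast_len(size + max_shift + 1)` per
  axis, which provably prevents circular aliasing for all lags inside the
  window;
- `max_shift` defaults to 20 px, twice the simulated ±10 px shake — a
  window keeps the cost down and suppresses spurious small-overlap peaks;
- lags whose overlap covers less than `min_overlap = 0.5` of the frame
  area, or where either variance term falls below `eps = 1e-12`, are
  masked invalid; overlap counts are rounded to integers before use;
- ties at the argmax resolve to the first occurrence in row-major order
  (deterministic).

A literal loop implementation (`ncc_spatial_oracle`) is retained purely as
a test oracle; the suite checks agreement with the FFT path at every
unmasked lag to 1e-6 on random frames.

### Subpixel refinement

A 1-D quadratic through the peak and its two axis neighbours, applied
independently per axis. The offsets are clamped to ±0.5 px — a well-formed
peak never needs more, and clamping bounds the damage of a degenerate
fit; an exactly flat triple (zero curvature) yields offset 0. If any of
the four neighbours is outside the window or masked, the integer peak is
returned with `integer_fallback` set.

### Template maintenance

The template lives in the filtered domain. It is initialized as the
high-pass-filtered temporal mean of a prerecorded movie (filtering the
mean rather than averaging filtered frames; the two are identical for a
linear filter up to boundary effects, and filtering once is cheaper).
During streaming, corrected filtered frames fill a buffer of capacity
k = 200; at capacity the template becomes `(template + buffer_mean) / 2`
and the buffer empties. The half-half blend keeps long-lived landmarks
while tracking slow drift in brightness or focus; k is configurable
(50–200 behaves equivalently on well-behaved data).

### Pipeline contracts

The stream loop is strictly causal: each output frame depends only on the
current frame and previously seen data, so outputs for frames ≤ t are
bit-identical whether or not later frames exist. There is no internal
randomness — identical input and configuration reproduce outputs exactly,
including the template trajectory. Frames are never dropped (one
registration record and one output frame per input frame). Output movies
match the input bit depth with clipping; `--float-out` preserves
real-valued frames for analysis. Movie I/O is multi-page grayscale TIFF;
AVI containers are not supported in this build.

## Synthetic data: what it emulates, and what it does not

The generator exists so that every claim can be tested against exact
ground truth. A scene (256×256 by default) is composed of:

- a heavily blurred background (white noise smoothed with
  `background_blur_sigma = 50` px, rescaled to [0.25, 0.55]) — the
  out-of-focus scatter that dominates one-photon frames;
- dark curvilinear vessels (random-walk centerlines stamped with ~2 px
  disks, 15% darkening) — the stable landmarks real registration locks
  onto;
- fine static tissue speckle (`texture_sd = 0.08`, grain sigma 1.5 px) —
  the high-frequency "mark point" texture that survives high-pass
  filtering in real recordings;
- an aperture vignette: a Tukey window re-leveled so the outer ~10 px of
  the sensor are truly black, as behind a miniscope lens. A useful side
  effect is that borders exposed by rigid shifts (zero-filled) meet an
  already-black rim, exactly as in recordings;
- 20 Gaussian-profile neurons of 10 px diameter (blob sigma = diameter/4),
  placed with ≥1.5-diameter spacing inside the fully illuminated region,
  resting amplitude 0.12.

Activity movies add, per frame: exponentially decaying calcium transients
(amplitude jump 0.25 per event, decay factor `transient_decay = 0.95` per
frame ≈ 1 s time constant at 20 fps; events Poisson with
`event_rate = 0.01` per frame per neuron ≈ 0.2 Hz), a global illumination
gain `1 + N(0, 0.01)`, an additive local background haze field — white
noise smoothed at the background scale, amplitude
`background_fluctuation_sd = 0.15`, faded toward the rim by a blurred
aperture envelope — and sensor noise `N(0, 0.01)`, with the rigid shift
applied last. The haze term models the large, spatially structured
background fluctuation characteristic of one-photon data; it is the
reason unfiltered NCC degrades on these movies (it perturbs the broad
correlation peak of raw frames) while the zero-sum filter removes it
almost entirely. All intensities are on a [0, 1) scale; movies written to
disk are quantized to 8 bits by default while ground-truth comparisons
always use the pre-quantization values.

Deliberately not modeled: photobleaching, nonrigid or rotational
deformation, raster-scan artifacts (two-photon specific), and hardware
frame drops. Passing tests on these movies therefore demonstrate the
geometry and statistics of the method — subpixel recovery accuracy, the
benefit of filtering, online/offline equivalence — but not robustness to
slow nonstationarities absent from the generator.

## Evaluation harness

The simulated-shift assessment mirrors the protocol a registration study
would use: build the template from a 60-frame motion-free prerecorded
activity movie; hold out one further activity frame (it carries its own
noise, transient state and haze snapshot, as any real frame would);
translate it n times by uniform offsets within ±10 px per axis (bilinear
resampling); run the full pipeline; report per-frame signed and absolute
per-axis errors and Euclidean deviations. Typical results at n = 500:
filtered median per-axis error 0.02–0.06 px, maximum 0.08–0.20 px;
the unfiltered ablation is consistently worse (paired one-sided Wilcoxon
signed-rank on per-frame deviations). `scripts/acceptance.py` runs
exactly this at n = 500 and writes the maximum (t1) and median (t2)
per-axis deviation.

The correlation-with-mean (CM) score evaluates real movies without ground
truth: crop a border (default: ceiling of the largest logged shift plus
one safety pixel), compute the temporal mean image, and report each
frame's Pearson correlation with it. Zero-variance frames are flagged NaN
rather than erroring.

## Traces and events

A neuron's trace is the mean over its circular ROI minus the mean over an
annulus (defaults: inner radius = ROI radius + 2 px, outer = +6 px),
which cancels frame-wide offsets and locally smooth background. The
subtraction direction is neuron-minus-background, the standard convention
that makes transients positive-going. Event thresholds default to
baseline mean + 3 SD from a prerecorded trace; an event is a complete
excursion — a rise strictly above threshold followed by a return to or
below it — timestamped at the return frame, and an excursion still open
at the end of a recording is not counted. The streaming detector keeps
only the open/closed state per ROI and is exactly equivalent to the batch
pass. Near-threshold noise can split one biological transient into
several brief excursions; threshold placement, not the detector, governs
that trade-off. Trace PSNR is defined as `20·log10(peak / noise_sd)` with
the peak measured above the baseline median and the noise SD taken over
out-of-excursion frames (any monotone alternative preserves the orderings
the tests assert). Power spectra are mean-removed one-sided periodograms
normalized so total power equals trace variance.

## Problem sizes

Default test and acceptance runs use 256×256 frames, 500-frame simulated
movies, 60-frame prerecorded templates and ≤240-frame activity movies —
sizes chosen so the whole suite completes in well under a minute while
every statistic (median/max over 500 frames, Wilcoxon at n = 500) retains
the power the claims need. The generator and pipeline scale to the
5,000-frame movies typical of real sessions without modification.

## Known limitations

- Rigid translation only; slow nonrigid deformation will register as a
  compromise shift.
- The parabola refinement is biased toward the integer grid when the
  correlation peak is extremely sharp (sub-pixel-wide), and toward zero
  offset when the peak is extremely flat; with the default filter on
  realistic scenes neither regime occurs.
- The unfiltered baseline exists for ablation studies, not production use.
- ROIs are circles; freehand masks and automatic neuron detection are out
  of scope, as are spike deconvolution and background-model decomposition
  (traces are exported in a form suitable for external deconvolution
  tools).
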