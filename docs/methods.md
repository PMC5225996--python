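# Methods

This note documents the models behind `sclerashg`, the design of the
synthetic-data generator the analyses are validated against, the tunable
parameters, and the package's numerical conventions and limitations.

## The measurements

**Waviness.** A fiber bundle's centerline is a polyline of sub-pixel
points; its waviness is the tortuosity ratio

    W = L_curve / L_linear

with `L_curve` the polygonal arc length along the trace and `L_linear` the
Euclidean distance between its endpoints. `W >= 1` by the triangle
inequality, with equality for straight fibers, and the ratio is invariant
under rigid motions and scale (both lengths carry the same `px ×
pixel_size` unit, 1 µm/px by default when calibration metadata is absent).
Per condition arm the hierarchy is: mean over the ~10 fibers of an image
field first, then mean and sample SD (n−1) over the ~10 fields. The image
field — not the fiber — is the replication unit. The treatment statistic is

    Waviness-% = 100 · (W_treated − 1) / (W_control − 1)

the residual waviness of treated fibers relative to paired controls
(below 100% = straightening). It is undefined when the control mean is 1
(perfectly straight controls); the implementation raises in that case. The
formula is evaluated on the condition means, as literally defined; a
per-image-ratio aggregation (mean over paired images of the per-image
ratio) is exposed as an option since the two differ for finite samples.
Significance uses a two-sided paired t-test on image-level means (images
are paired by animal in the synthetic design; an unpaired Welch test is
available for designs without pairing), α = 0.05 throughout.

**Mean pixel density.** Brightness is the mean of an image's intensity
histogram with one bin per integer level over the full bit range and no
normalization — making it *exactly* the pixel mean (both are computed by
integer accumulation and tested for identity). Paired analysis: per-animal
treated-minus-control differences, mean ± sample SD, two-sided paired
t-test. Dose analysis: a linear mixed model `mean ~ condition + (1 |
animal)` fitted by maximum likelihood (REML behind a switch), Wald
inference on all pairwise condition contrasts, no small-sample df
correction. In the balanced paired design the GLS fixed-effect contrast
reduces algebraically to the simple mean of within-animal differences,
whatever the variance components; this equivalence is asserted to 1e-8 in
the tests. Wald p-values are asymptotic: with very few animals they run
slightly anticonservative, which the null-calibration test therefore
exercises at a comfortable group count.

**Sector ΔTm.** Tm tables hold one row per (animal, sector ∈ 1..16) with
treated and control peak denaturation temperatures. Per sector: mean and
sample SD of within-animal differences and a two-sided paired t-test; the
sorted significant sectors form the zone of effect. No multiple-testing
correction is applied by default — the per-sector raw paired t-tests are
the reported quantity — with Bonferroni and Benjamini–Hochberg available
as options. Zero-variance differences (possible at noise 0) are reported
as degenerate rather than crashing: p is NaN and the significance flag
takes the noise→0 limit (significant iff the mean shift is nonzero).

## The synthetic generator

The generator emulates the statistical structure of a paired-eye scleral
crosslinking experiment, not its optics. Design goals: every expectation
the tests assert should be available in closed form, and all output must
be bit-reproducible from one integer seed (numpy `SeedSequence` spawning:
one child per animal, grandchildren per eye).

**Centerlines** are single-frequency sinusoids on a straight chord:
`y = A sin(2π k s / L + φ)` with integer cycle count `k` (2 by default),
random phase φ and orientation per fiber. An integer `k` pins the
endpoints so the chord is exactly `L`; the amplitude `A` is solved by
bisection so the polygonal arc/chord ratio of the sampled polyline
(spacing 0.5 px along the chord) equals the requested waviness to < 1e-6.
The independent cross-check in the tests evaluates the continuous arc
length through the complete elliptic integral of the second kind.

**Rendering** uses a flat-top cross-profile by default: every pixel whose
center lies within `width/2` of the centerline gains the fiber's peak
intensity (additively, on a constant background). The expected pixel count
of such a tube under uniformly random sub-pixel placement equals its exact
area, `w·L·W + π(w/2)²` (rectangle along the arc plus two half-disk end
caps), so the expected image mean is

    E[mean] = background + peak · n_fibers · (w·L·W + πw²/4) / n_pixels.

Tube membership is computed exactly: a coarse point-distance pass
classifies all pixels whose distance verdict is unambiguous, and the thin
boundary band left over is re-tested against the actual polyline segments.
A Gaussian profile (FWHM = width) is available as an option, without the
closed-form mean. Fibers are placed by rejection sampling with a minimum
centerline clearance so tubes never overlap (preserving linearity of the
mean in fiber count); a per-fiber cap of 1000 rejections raises an error.
Rendered values are clipped to a 12-bit payload (0–4095) in a 16-bit
container and rounded once at the end, after noise.

**Variance structure.** Three zero-mean components on top of the pixel
noise model (`none`, `gaussian(σ)`, or `poisson + gaussian(σ_read)`;
default gaussian σ = 20 counts):

* a per-animal brightness intercept (SD 10 counts) shared by both eyes —
  this is what makes the random-intercept model non-trivial;
* a per-eye brightness intercept (SD 8 counts) — field-to-field
  variability, without which paired differences would be unrealistically
  precise (their SD would be set by placement jitter alone, ~0.2 counts);
* the pixel noise itself, whose contribution to an image mean is
  negligible at ~10⁶ pixels.

Per-animal and per-eye intercepts shift the whole image, so they cancel
from the expected paired difference; the paired-difference SD is therefore
≈ √2 · 8 ≈ 11 counts under the defaults.

**Presets.** Named presets pin the ground truth to the reported results so
round-trip recovery is meaningful:

| preset | ground truth | geometry |
| --- | --- | --- |
| `cfg-int-40` / `cfg-int-400` | mean-density difference 66.3 / 361.4 counts | 30 fibers, w 10 px, L 300 px, W 1.30 both arms |
| `cfg-int-null` | difference 0 | as above |
| `cfg-wav-40` / `cfg-wav-400` | W 1.300 control vs 1.189 / 1.165 treated (→ 63% / 55%) | 10 fibers, w 8 px, L 400 px |
| `cfg-tm-40-insitu` / `cfg-tm-400-insitu` | sector-2 shift 4 / 13 °C | n = 3 animals, noise 0.5 °C |
| `cfg-tm-40-map` | sectors 1–3 shifted 3.4 °C | idem |
| `cfg-tm-400-map` | sectors 1–9 at 19 °C, 10 and 14 at 2 °C | idem |

Brightness presets fix the control peak (500 counts on background 150) and
invert the treated peak from the target difference through the tube-area
formula, so `expected_mean_difference` is analytic by construction at any
image size. Only the *ratio* statistic is anchored for waviness (absolute
waviness of sclera is not a reported quantity; 1.300 for controls is this
package's documented convention). Two choices depart from the simplest
scheme for the brightness presets specifically: 4 sine cycles (same arc
ratio, half the amplitude) and locally aligned fiber orientations
(per-image base direction with 10° normal spread, as scleral bundles run
quasi-parallel within a field). Both keep rejection-sampling placement
comfortably feasible at the ~11% area coverage the 361.4-count target
forces within the 12-bit range — isotropic long sinusoids jam against the
rejection cap there — and the alignment is the more realistic texture.
Waviness presets are sparse and stay isotropic with a wider clearance
(2.5 × width) so traces never feel a neighboring fiber.

**Tm tables** are direct draws: control ~ `baseline + N(0, σ)`, treated ~
`baseline + shift(sector) + N(0, σ)`, baseline 65 °C, σ = 0.5 °C, n = 3
animals by default.

## The tracer

Manual mouse tracing is replaced by a deterministic bidirectional ridge
follower. From a seed point (on synthetic data: the ground-truth
centerline midpoint from the manifest; on real images: the strongest
smoothed-intensity grid points under a mutual-separation constraint):

1. Initial direction from the structure tensor of a local window (2× the
   normal half-width): the eigenvector of the smaller eigenvalue points
   along the ridge; near-isotropic neighborhoods fall back to the +x axis.
2. Each step advances `step_px` (default 2) along the current direction,
   then re-centers on the background-subtracted intensity centroid sampled
   along the normal (half-width default 12 px ≈ 1.5 × fiber width, 0.5 px
   sampling). The centroid is averaged over three parallel normal lines
   (±1 px along the tangent): a single line shows a moiré-like centroid
   oscillation at oblique orientations under bilinear interpolation, which
   destabilizes the heading. The shift is clipped to 0.45 × half-width.
3. Termination: image border; intensity below `stop_fraction` (default
   0.5) of the background-subtracted seed intensity — checked both before
   re-centering (otherwise the centroid slides around the bright
   semicircular end cap and the trace U-turns) and after; per-step turn
   above `max_turn_deg` (default 30°), measured against the previous
   realized step (the inertia-smoothed heading lags on curves and would
   trip the limit spuriously); or `max_steps` (default 2000).
4. The two half-traces are concatenated and lightly smoothed (centered
   3-point moving average, endpoints untouched). Sub-pixel interpolation
   jitter otherwise inflates the polygonal arc length by up to ~1% of the
   ratio; the smoothing window is short enough (≈6 px against sinusoid
   wavelengths of 100–200 px) that real amplitude attenuation is < 0.1%.

On noise-free renders across waviness 1.0–1.4, orientations and phases,
traced centerlines sit within 0.5 px RMS of ground truth (the residual is
dominated by the trace legitimately following the bright end caps a few
pixels past the chord ends) and the traced ratio is within 0.4% of truth;
the acceptance suite asserts 0.5 px / 1%.

Crossing fibers are resolved by the straightest continuation (the turn
gate), mimicking a human following "the same" bundle; the synthetic
presets avoid crossings entirely via the clearance constraint, so this
path is exercised only by the gate itself.

## Numerical conventions

* Coordinates: (x, y) = (column, row), 0-based, pixel centers at integers.
* Sample SD (n−1) everywhere; two-sided tests; α = 0.05.
* Waviness is reported to one decimal in CLI output; full precision in
  JSON.
* Degenerate inputs: all-zero paired differences give p = 1 (no effect, no
  evidence against the null); zero-variance *nonzero* differences raise a
  degenerate-test error (paired t undefined) — except per-sector tests,
  which flag instead of raising so one degenerate sector cannot abort a
  16-sector map. A fiber chord below 1 px raises rather than returning an
  unstable ratio.
* Amplitude bisection tolerance 1e-9 on the ratio; tube-membership band
  width `h²/(8r)` with `h` the polyline segment length — outside the band
  the point-distance verdict is provably correct, inside it the exact
  segment distance decides.
* All stochastic pipelines take one integer seed; replicate seeds are
  derived via `SeedSequence.generate_state` (31-bit).

## Problem sizes in the validation suite

Round trips run at the nominal study scale: 1024² images, 10 pairs (or 10
images per arm) per replicate, 20 replicate seeds, with Tm tables at n = 3
animals. Unit tests and the null-calibration run (100 replicates) use
geometrically scaled-down configurations (192²–256² images, 6–8 shorter
fibers at matched ~11% coverage) whose analytic expectations rescale
exactly; the per-eye/per-animal variance structure is size-independent.

## What the generator does not emulate

No optical physics: no point-spread function, no polarization-dependent
SHG yield, no depth sectioning or 3-D stacks, no detector gain curve
(noise is plain Poisson/Gaussian). No biological texture beyond fiber
bundles: no vasculature, cells, or background autofluorescence gradients;
fiber width and peak intensity are constant within an arm rather than
distributed; centerlines are single-frequency sinusoids rather than the
broadband undulations of real collagen; bundles never cross. Consequently,
passing round trips demonstrate that the *measurement pipeline* is
unbiased and correctly calibrated on images whose statistical structure
(paired design, variance components, contrast and waviness levels) matches
the study — they do not certify tracer performance on real micrographs
with crossing bundles, intensity inhomogeneity, or depth-dependent blur.
The absolute waviness scale and all intensity magnitudes are documented
conventions, not measured tissue properties.

## Known limitations

* The tracer requires curvature radius comfortably above its step length
  (ratio targets near 1.4 on fibers much shorter than ~200 px curve too
  tightly and terminate early by the turn gate).
* Wald mixed-model inference is asymptotic in the number of animals; for
  n ≈ 10 animals its type-I rate runs a few points above nominal, which is
  why the paired t-test is the primary inference in the paired design.
* The sector analysis treats sectors independently (as does the reported
  procedure); no spatial smoothing or diffusion model links adjacent
  sectors.
* `select_seeds` (real-image mode) is intensity-greedy and will seed
  multiple traces on one very bright bundle if the separation constraint
  allows; the synthetic pipeline always seeds from the manifest.
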