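# Methods

This note documents the measurement model, the synthetic-data
generator, the numeric choices, and the limits of what the tests show.

## Phantom model and coordinates

The phantom is modeled as a 200 mm diameter, 160 mm long cylinder of
water-equivalent material (0 HU) in air (−1000 HU), divided into four
40 mm modules. All in-plane positions are mm relative to the phantom
axis (x right, y toward increasing row index); z is the DICOM slice
position, with module centers at 0/40/80/120 mm relative to the
module-1 plane. Exact in-plane insert coordinates are not standardized
in the analysis literature at the millimetre level, so they are
configuration (`PhantomGeometry`), with defaults that place the four
outer plugs at the cardinal positions at 60 mm radius, water at the
center, rods in the upper half of module 2 at 50 mm radius, distance
BBs at (±50, 0) mm, and eight bar patterns on a 60 mm ring. What the
metrics require is only that renderer and analyzer share one geometry;
the analyzer never reads simulator internals, only this shared
description and the image.

The accepted HU range per plug ships as configuration taken from ACR
CT accreditation documentation (air −1005…−970, polyethylene −107…−84,
water ±7, acrylic 110…135, bone 850…970); these ranges are not part of
the two-year reference dataset bundled with the package.

## Localization

- Phantom body: largest connected region above −300 HU per slice,
  hole-filled (the air plug would otherwise bias the centroid), with
  its geometric centroid as the per-slice center. −300 HU sits safely
  between air (≈−1000) and every phantom material, and a constant HU
  miscalibration of less than a few hundred HU cannot move it across a
  material boundary (tested at ±100 HU).
- BBs: 3D connected components above +800 HU with a 500 mm³
  small-object cap (the bone plug is far larger and is rejected by the
  cap, not the threshold). Centroids are intensity-weighted above the
  threshold, which is what gives sub-pixel distance accuracy.
- Roll: detections on the alignment-BB ring near the module-1/4 planes
  are assigned to the nominal BB with the nearest polar angle; the
  roll is the mean wrapped angular deviation. Rolls beyond a 5° guard
  are flagged as probable setup errors rather than silently corrected,
  mirroring clinical practice of re-setting up a visibly rotated
  phantom. ROI templates are counter-rotated by the estimated roll.
- Analysis slices: modules 1 and 4 use the slice with the most visible
  alignment BBs; module 3 the slice holding both distance BBs; module
  2 the slice nearest its mid-plane. If BBs are unmatched (e.g. very
  low-dose modes), slices fall back to nominal 40 mm offsets from the
  phantom z mid-plane and the session is flagged. "Visible" means
  detected above the threshold — an automated surrogate for the
  window/level judgement a human makes.

A volume whose z extent cannot contain all four modules is analyzed
best-effort from the leading face with an `incomplete_phantom_coverage`
flag; metrics of uncovered modules are reported not-evaluable.

## Metrics

ROI statistics use pixels whose centers fall inside the circle (simple,
deterministic, converges as spacing → 0; rasterized area is within 5%
of nominal at ≤1 mm spacing) and the n−1 sample SD. ROIs that overlap a
supplied artifact mask by more than 30% are re-seated by searching
angular offsets about the phantom axis (±30° in 5° steps) for the
placement with the least masked area — the automated version of
"place the ROI off the crescent artifact".

Two formula details deserve pinning. CNR is
`|ROI_mean − BG_mean| / BG_SD` with the water plug of the same slice as
background; it is invariant to a global HU shift. Noise is
`100 × SD / (mean + 1000)`; the +1000 HU rescale puts the denominator
on an attenuation-like scale and makes the metric deliberately
*sensitive* to HU calibration shifts — both properties are asserted in
the tests.

Slice thickness uses the wire-ramp count: candidate wire sites are
sampled by bilinear interpolation along each ramp, the ramp background
is the median site value, wires with contrast above half the maximum
contrast count as visible, and thickness = 0.5 mm (the z-pitch) times
the mean count over the two ramps. The simulator's wire grid is offset
a quarter pitch from the module plane so a slab of width T centered on
the plane contains exactly T/0.5 wires; with an aligned grid the edge
wires would sit exactly on the slab boundary and the count would be a
coin flip.

Rod visibility is `contrast > k × background SD` with k = 1 by
default, mirroring the CNR ≥ 1 acceptance idea; the local background is
the pooled pixel population of same-size ROIs interleaved between the
rods on the same ring. Zero visible rods is a legitimate result and is
the expected one at CBCT noise levels.

High contrast: the modulation statistic of a pattern is the SD of HU in
a circular ROI inside the pattern square, corrected by default for the
noise floor (the SD of a same-size ROI at the uniform module center,
subtracted in quadrature). Without the correction, heavy noise puts a
floor under every pattern's SD and fine patterns can never "wash out";
with it, the statistic approximates the signal modulation. A pattern
resolves if its statistic exceeds 0.4× the coarsest pattern's; the
scan runs coarse to fine and stops at the first failure, making the
score monotone by construction. If the coarsest pattern's raw SD is
below 1.5× the noise floor the metric is not evaluable. The 0.4 and
1.5 constants are exposed in `MetricSettings`; they were chosen so
that the analyzer reproduces the qualitative CT-vs-CBCT resolution
behavior on the synthetic presets and are numeric surrogates for a
human's bar-counting judgement, not measured constants.

## Tolerances and trending

`derive_tolerances` computes, per metric, the sample SD within each
(machine, protocol) group between baseline resets and sets the bound at
2× the maximum group SD, rounded half-away-from-zero at the metric's
reporting precision (nearest HU for HU and uniformity values printed as
integers — uniformity keeps one decimal so a 0.7 HU max SD gives ±1.4;
one decimal for CNR; two for noise %). Normality is assumed, not
tested; under it a result falls outside the band ~5% of the time, so a
flag means "investigate", and a single-machine program should expect
occasional statistical false alarms. A deviation exactly equal to the
bound passes ("outside the band" flags). All-identical histories yield
bound 0 with a `degenerate` flag. Baselines default to the first
session of a segment (`k = 1`); `k > 1` averages the first k sessions
(the preliminary mode used when only a few quarters of data exist).

`reference_tolerances(modality)` derives the shipped defaults from the
bundled two-year reference program data at call time: CNR and noise
bounds from the per-protocol mean/SD tables, HU/uniformity/distance
bounds from the published maximum SDs, plus the fixed recommendations
(slice thickness ±0.5 mm of nominal, distance ±1.0 mm of 100.0 mm,
high contrast ±1 lp/cm of baseline, CT plug HU ±3 HU, low-contrast CNR
≥ 1.0 and within 0.4 of baseline). Two cells of the published CBCT
recommendations (acrylic CNR ±3.3, acrylic noise 0.87%) are slightly
larger than 2× the corresponding table SDs (3.2, 0.86), most likely
rounding of unprinted intermediates; this package reports the computed
values. The CBCT bone plug's observed max SD (29.1 HU) is inconsistent
with any usable published bound, so no default bone tolerance ships —
it must be configured explicitly.

`monitor` evaluates sessions in order and, when a delta-mode action
fires, starts a new baseline segment at the next session — the
investigate/recalibrate/re-baseline loop. `trend_report` and the trend
plots summarize per-segment mean ± 1 SD with reset markers.

## The synthetic generator

`render_phantom` draws the ideal HU map per slice (plugs, rods, bars,
wires and BBs as partial-volume-weighted blobs), applies a Gaussian PSF,
adds artifact fields, adds i.i.d. Gaussian noise, and rounds to
integral HU (what scanners export; also what makes the DICOM round
trip lossless). Bar patterns are pixel-aperture averaged in x before
blurring — point-sampling a square wave would alias full-amplitude
patterns at any frequency. Cupping is a radial parabola scaled so its
amplitude equals the analytic center-vs-edge-ROI uniformity difference,
which makes "uniformity ≈ cupping amplitude" exact by construction and
gives a closed-form oracle (`expected_uniformity`). The ground-truth
log records artifact-adjusted expected ROI means per plug so that
recovery is well-defined with artifacts on.

Presets encode the study conditions rather than acquisition physics:

| preset | σ (HU) | PSF σ (mm) | cupping (HU) | emulates |
|---|---|---|---|---|
| `ct-sim` | 3.5 | 0.45 | 0 | fan-beam CT simulator |
| `cbct-head` | 30 | 0.40 | 20 | full-fan head CBCT |
| `cbct-pelvis` | 30 | 0.80 | 30 | half-fan body CBCT |

σ = 3.5 HU gives plug noise ≈ 0.4% and plug CNR ≈ 25–35 (clinical CT
scale); σ = 30 HU gives ≈ 3.3% and CNR ≈ 3 with invisible 6 HU rods
(linac CBCT scale). The PSF widths were fixed by scanning the analyzer
over noiseless renders so the presets sit at 6, 7 and 4 lp/cm — the
resolutions reported for those modes. Defaults: 384×384 matrix at
0.65 mm pixels, 2.5 mm slices, 3 mm BBs at 3000 HU, 700 HU wires,
6 HU rod contrast (0.6%), 1000 HU bar amplitude.

What the generator does **not** emulate: correlated/streak noise,
beam hardening, scatter fields, ring artifacts, gantry sag, or any
kVp/mAs dependence (protocol parameters are labels only). Passing
tests therefore demonstrate that the analysis pipeline is correct and
unbiased under controlled degradations of realistic magnitude — not
that it is robust to every real CBCT artifact. `simulate_longitudinal`
applies per-session linear drift and step events (with optional
baseline-reset semantics) and seeds each session as `seed + session`.

## Problem sizes and numerics

Tests and the acceptance script run full 63-slice, 384² volumes
(seconds per render/analysis on one CPU); multi-seed recovery checks
use 20 seeds on single-module crops. Statistical assertions are sized
to the estimators' sampling distributions (e.g. plug-mean SE =
σ/√473 pixels) with fixed seeds. Ties and degenerate inputs: a
noiseless render can leave the background SD at exactly 0, making CNR
not-evaluable by definition; ROI re-seat prefers the smallest angular
offset; boundary-equal deviations pass; rounding is half-away-from-zero
so 2×7.9 → 16.

## Known limitations

- No pitch/yaw estimation (flagged setups should be re-acquired, not
  corrected); no MTF estimation (discrete lp/cm patterns only).
- HU results from this single-orientation, head-size phantom must not
  be used to build HU-to-electron-density curves for dose calculation.
- The artifact mask is an input (from configuration or the simulator's
  ground truth); the package does not auto-segment crescent artifacts.
- Compressed DICOM transfer syntaxes and non-axial reformats are out of
  scope.
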