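# Methods

## The measurement model

A field device is a laminated strip of Whatman-type filter paper carrying
eight wax-printed 10 mm circular zones inside a rectangular wax box. Six
zones are pre-loaded with the phosphomolybdenum-blue (PMB) reagents
(molybdate/antimony plus ascorbic acid); two are left empty as negative
controls ("blanks") whose colour after dipping reflects only the water
itself. Beside the wax box sit a printed saturated-blue internal-standard
square and a plain laminate area, plus a four-digit device code.

Quantification works on an ordinary RGB photograph of the whole card.
For any region, the *average intensity* is

    AI = mean over the sampled mask of (255 − gray),   gray = Rec.601 luma,

so deeper blue development gives a larger AI. Each detection zone yields

    ARI = (AI_reaction − AI_blank) / AI_ref                            (per zone)

with `AI_blank` the arithmetic mean of the two blank zones and `AI_ref` the
internal-standard intensity measured **relative to the plain laminate patch
beside it**, `AI_ref = AI(blue square) − AI(laminate)`. A device reading
reports the six per-zone ARIs and their mean ± sd.

### Why the reference is background-subtracted

Under a multiplicative illumination gain *g* (scanner vs phone, sun vs
shade), every pixel maps as v → g·v. Differences of AI values scale exactly
with *g*, while a raw inverted intensity (255 − g·v) does not. Measuring the
reference square against the adjacent laminate makes the denominator a
difference too, so ARI is *algebraically* invariant to gain (and to any
additive offset): the property the printed internal standard exists to
provide, and the property the test suite asserts to 1e-6. An additive water
tint that darkens reaction and blank zones equally cancels exactly in the
numerator; a tint that also covered the reference/laminate area would not,
which is why the reference region sits outside the porous wax box.

### Zone registration

The layout is registered to the photograph rather than zones being detected
freely, so the blank/detection role of every zone is inherited from the
printed design and never inferred from colour. Canny edges feed a Hough
circle transform over radii ±15% around the expected zone radius; the eight
layout centres are matched to detections by nearest neighbour after
centroid/scale alignment (three refinement rounds), each matched centre is
refined to sub-pixel precision as the darkness centroid of the wax ring in
an annulus window, and a similarity transform (scale, rotation ≤ 10°,
translation) is estimated from all eight. Reported centres are the
transform's predictions, so a single weak detection cannot displace its
zone. Typical accuracy on synthetic images is < 0.1 px; the contract tested
is < 2 px. Fewer than eight matchable circles raises a detection error; a
mean residual above max(3 px, 8% of the zone radius) raises an alignment
error.

Intensity is sampled over the inner 70% of each zone radius (edge exclusion
for wax-wicking artefacts; configurable) and over a disc inscribed in the
reference square and laminate patch. Zones with > 1% of pixels at the 8-bit
extremes are flagged `saturated`, not rejected.

## Calibration and limits

ARI responds linearly to concentration over the regulatory-relevant
0–10 mg L⁻¹ range (the dose response is Michaelis-like with half-saturation
≈ 40 mg L⁻¹, so curvature within 0–10 is mild and absorbed by OLS). The
model stores slope, intercept, residual sd, the sd of the c = 0 replicates
(σ_blank), and R². A log-linear form is available for wide-range
(1–1000 mg L⁻¹) demonstration sets. Calibration replicates are
**device-level** ARI means (mean of the six zones of one card), matching
how replicate error is reported for this device class.

Detection limits use the ICH-style convention LOD = 3.3 σ_blank/slope and
LOQ = 10 σ_blank/slope. The device's published limits (3 and 8 mg L⁻¹)
have a ratio matching no standard convention; this package documents its
convention and treats the published pair as upper bounds: under default
generator conditions the computed limits land near 1.5–2.5 and 4–7 mg L⁻¹.

Inverse prediction is ĉ = (ARI − intercept)/slope with first-order
propagation of the reading's sd/√n and the calibration residual sd; values
above the top of the calibrated range raise an error rather than
extrapolate. Estimates below LOD keep their numeric value (maps need it)
but carry a `<LOD` label.

Bracket classification rounds half-up to the nearest integer and maps
0 → none, 1–3 → low, 4–6 → medium, ≥ 7 → high. Rounding first closes the
gaps the printed brackets leave between 3 and 4 and between 6 and 7, and
makes the classifier monotone and exhaustive on c ≥ 0.

The blank-equivalence test is Welch's two-sample two-tailed t (unequal
variances; the safer default when only "two-tailed t-test" is specified),
with the critical value at Welch–Satterthwaite degrees of freedom. Method
comparison rounds both estimates to one significant figure (half away from
zero) and reports the agreement fraction; note this statistic is
intrinsically grainy when an estimate falls near a significant-figure bin
edge. Plateau time is the earliest sample at which intensity reaches
(1 − tol) of the plateau, the plateau being the mean of the last two points
(default tol 0.05).

## The synthetic-data generator

Because the field campaign's raw photographs are not published, the
generator is the package's test bed. It emulates:

- **Kinetics** — S(c, t) = blank_level + a_max · c/(c + K_half) ·
  (1 − e^(−k_rate·t)). Defaults a_max = 0.55, K_half = 40 mg L⁻¹,
  k_rate = 1.5 min⁻¹, blank_level = 0.02. With k_rate = 1.5 the signal
  reaches 1 − e^(−4.5) = 98.9% of its asymptote at 3 min, reproducing the
  observed "develops for ~2 min then plateaus" behaviour and justifying the
  3-minute field incubation. blank_level models molybdate auto-reduction in
  reagent-loaded zones and becomes the calibration intercept; only with
  blank_level = 0 do detection and blank zones render identically at c = 0.
- **Colour** — the blue complex attenuates R and G by (1 − S) and B by
  (1 − 0.15 S) on paper of reflectance grey 210 (chosen with headroom so a
  ±20% illumination swing never clips white pixels); the reference square
  prints as RGB (0, 20, 160). These constants give an effective calibration
  slope ≈ 0.011 ARI per mg L⁻¹ over 0–10 mg L⁻¹.
- **Replicate dispersion** — per-zone Gaussian signal jitter
  (`zone_noise_sd`, default 0.0068 signal units ⇒ within-device ARI sd
  ≈ 0.007 at blank) plus per-pixel camera noise (default sd 2 counts).
  Zone-level jitter models reagent-deposition and paper heterogeneity and
  dominates, because pixel noise averages out over ~10³-pixel masks.
- **Capture** — multiplicative gain, a linear horizontal gain gradient
  (phone vignetting; a few per cent is realistic — note that a strong
  gradient genuinely biases ARI because the blanks do not share each
  detection zone's position), additive offset, subtractive per-channel
  water tint inside all porous zones, and rotation up to ±10°. No
  perspective warp, JPEG artefacts or radiometric camera model.
- **Interferents** — silicate uses the same dose–response with the rate
  scaled by `rate_multiplier` (default 0.005), so 1000 mg L⁻¹ silicate at
  3 min sits within 0.012 of a blank, while long incubations would develop
  it — matching the known slow silicomolybdate chemistry.
- **Campaigns** — records with uniform GPS in a bounding box, uniform UTC
  timestamps, true concentrations lognormal (median 3 mg L⁻¹, log-sd 0.7 —
  a realistic spread for nutrient-enriched lowland waterways, spanning all
  four brackets) modulated by a sinusoidal seasonal term in log space
  (default amplitude 0.4, peak mid-July), and a user slider reading that
  tracks the truth with ±1 noise.

Everything stochastic derives from an integer seed (NumPy `SeedSequence`
children per image), so images and record sets are bit-reproducible.

What passing tests on this generator do **not** show: robustness to
perspective distortion, specular glare, shadows, heterogeneous wicking,
reagent ageing (exposed only as an optional a_max attenuation), or OCR of
device codes (codes are transcribed manually). Field performance on real
photographs can be worse than the synthetic figures in exactly these ways.

## Numerical and design choices

- Pixel (ix, iy) has centre (ix + 0.5, iy + 0.5); mm → px via a single
  scale; device frame origin top-left, y downward. Masks are exact
  point-in-circle sets on pixel centres (tested against brute force).
- Zone arrangement: 4 × 2 grid, 14 mm pitch, 62 × 34 mm wax box on an
  80 × 50 mm laminate, blanks at the bottom-right pair; reference square
  8 × 8 mm right of the box above an 8 × 8 mm laminate patch. Only the
  10 mm zone diameter is fixed by the device definition; the rest is this
  package's canonical layout, shared by generator and quantifier (which is
  all the analysis needs) and configurable via the YAML layout file
  (`layout_version: 1`).
- `quantify_scene` quantifies with known geometry (a generator truth
  sidecar), skipping circle detection; it is used where the quantity under
  test is intensity extraction or calibration, not registration.
  `quantify_device` always runs full registration.
- Default problem sizes: renders at 5 px/mm for bulk work (10 px/mm for
  registration-accuracy checks), calibration sets of 11 × 6 devices,
  20-seed recovery studies, 50-record campaigns. These keep a full test +
  acceptance run to a couple of minutes while leaving Monte-Carlo error
  well below the asserted tolerances.
- QC flags annotate and never block. The pigmented-water flag compares the
  blanks' excess darkness over the laminate, normalised by AI_ref
  (illumination-invariant), against a 0.1 threshold.
- Timestamps without an offset are assumed UTC and flagged. Record parsing
  is lossless: accepted rows re-serialize byte-identically, and accepted +
  rejected always partitions the input file.
- Campaign bracket accuracy under default noise is ≈ 80–90%: the dominant
  error is the ~0.5 mg L⁻¹ estimate noise against 1 mg L⁻¹-wide bracket
  rounding boundaries, so misassignments are to adjacent brackets only.

## Known limitations

- The linear calibration under-reads above ~10 mg L⁻¹ (dose-response
  curvature); readings beyond the calibrated response are refused, not
  extrapolated, and strongly developed devices should be re-read against a
  wide-range log-linear calibration.
- The ARI's blank subtraction assumes the water tint is spatially uniform
  across the card; a strong illumination *gradient* (≳ 5% across the card)
  biases ARI because blanks and detection zones occupy different positions.
- The 1-s.f. method-agreement statistic is a coarse instrument near bin
  edges; disagreement there does not imply a calibration fault.
- The Welch test at α = 0.05 will, by construction, call ~5% of true blank
  pairs "distinguishable".
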