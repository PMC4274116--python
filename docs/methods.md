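# Methods

`massdivide` analyses time-lapse quantitative phase images (QPI / live-cell
interferometry) of dividing cells.  Pixel values are optical path difference
(OPD) in nanometres; because OPD integrated over a cell's footprint is
proportional to its dry mass through the specific refractive increment
α = 1.8×10⁻⁴ m³/kg,

    m [pg] = Σ_pixels OPD[nm] · A_pixel[µm²] · 10⁻⁶ / α,

a phase movie is a movie of single-cell dry masses.  The pipeline runs five
stages — phase unwrapping, cell segmentation and mass measurement, track
linking, division detection, and mass-partitioning statistics — and every
stage is validated against a synthetic movie generator that knows the ground
truth.

## Synthetic phase movies

`synthetic.CellScenario` programs one cell's life history; `simulate_movie`
renders a seeded movie plus a `GroundTruth` ledger (per-frame true masses,
wrap masks, event times, true daughter asymmetry Δm(t)).

Cells are super-Gaussian OPD profiles, exp(−(r/R)⁶).  The peak is chosen so
the *discrete* integral equals the programmed mass, so ledger mass and
integrated OPD agree to machine precision and mass is conserved by
construction.  The order-6 profile has a plateau top and a steep skirt:
touching daughters form a clean OPD saddle and little mass sits below the
segmentation floor.

Defaults emulate the experimental conditions the analysis is designed for:
240×320 µm field at 1 µm/px, 3-min frame interval, 530 nm wavelength,
initial mass 300 pg (mammalian-line scale), growth 0.3 pg/min (roughly one
doubling per 17 h), additive Gaussian background noise of 3 nm (OPD noise is
not published for these instruments; 3 nm keeps single-frame mass noise well
below 1 pg for a typical footprint while remaining visible in images).

Adherent cells flatten/round with a logistic radius transition between
`flat_radius` (12 µm) and `round_radius` (5.5 µm), time constant 6 min: mean
phase shift (mass per area) therefore rises sigmoidally before division and
decays after, and the rounded peak OPD (~650 nm) exceeds the wavelength so
the unwrapping path is genuinely exercised.  The generator keeps true OPD
below 2λ, matching the single-correction regime the unwrapper implements.
Non-adherent cells keep a fixed radius.

A division replaces the parent with two lobes whose mass fractions are
(f, 1−f) at the furrow.  Lobe spacing is 2.2× the mean lobe radius — close
enough to overlap (an OPD saddle, as in late cytokinesis) but far enough for
two watershed maxima.  Optional redistribution transfers a linear fraction of
the pair mass per minute between the connected daughters for a fixed
duration; the ledger Δm(t) = 2(m₁−m₂)/(m₁+m₂) follows analytically.

What the generator does **not** emulate: interference fringes and coherent
imaging artifacts, cell migration beyond stationarity, debris, overlapping or
crossing cells, focus drift, and shape irregularity.  Passing tests therefore
demonstrate the correctness of the measurement chain under the stated optics
model, not robustness to every failure mode of real microscopy.

## Phase unwrapping

Interferometric phase is reported modulo one wavelength, so a rounded
mitotic cell appears with a λ deficit inside a closed contour.  Unwrapping
is a two-class pixel classification: 16 per-pixel statistics (raw OPD,
intensity, a phase-quality map — windowed variance of the gradient
magnitude — Sobel h/v/magnitude, Laplacian, Gaussian-smoothed OPD at σ = 2
and 8 px, local standard deviation in 3- and 7-px windows, local range,
median-filter residual, morphological gradient, intensity-gradient
magnitude, and wrap proximity λ−OPD) feed a linear discriminant trained to
recognise the *inner boundary ring* of wrapped regions.  Training labels come
from the generator's wrap masks, replacing manual annotation with the same
two-class formulation.

The decision threshold maximises balanced accuracy on a stratified 20%
held-out split and is then centred in the local score margin.  At detection
time, supra-threshold outlines are closed and hole-filled; the filled
interior seeds the wrapped class, sub-threshold pixels outside it seed the
background, and a random walker on the normalised score image (β = 130)
assigns the remaining band.  `correct_phase` then adds exactly +λ inside the
mask — only single, positive corrections, mirroring the regime in which
multiple or negative corrections are rare.  The correction is not
idempotent; re-application requires re-detection.

## Segmentation and mass

Frames are smoothed with a Gaussian (σ = 2 px).  Within each connected
foreground component (smoothed OPD > 8 nm floor), an Otsu threshold sets the
level above which h-maxima (h = 8 nm) count as individual cells; those
maxima seed a watershed on the inverted smoothed image, which splits touching
cells along the OPD ridge.  Regions below 50 µm² are discarded.  Mass sums
the **raw** OPD over the segmented footprint (smoothing is for geometry
only), keeping the mass estimate unbiased.  Per-component Otsu is used
because a single global threshold drops dim spread cells whenever a bright
rounded cell is in frame.

Shape factor is 4πA/P² with P the weighted contour length from
`skimage.measure.regionprops` (the equivalent of MATLAB regionprops
`Perimeter`): a digitized circle scores ≈ 0.93 and a square ≈ π/4, and the
value never exceeds ~1.1.  A raw boundary-pixel count was rejected because it
pushes a circle to ≈ 1.25.  Confluence is the percentage of nonzero label
pixels.

## Tracking

Between consecutive frames the one-to-one assignment minimising total
squared centroid displacement is computed (Hungarian algorithm), gated at
20 µm/frame; unmatched regions start or end tracks and there is no gap
closing.  The cost is purely positional, but a link whose mass ratio leaves
[0.7, 1/0.7] is severed: at the furrow the watershed suddenly reports a
half-mass object where the parent was, and carrying the parent identity onto
one daughter would make divisions invisible to the detector.  Ties resolve
by label order, so re-runs are identical, and the assignment equals
brute-force enumeration for small frames (tested to 6 cells).

## Division detection

A division event requires, for adherent cells:

1. the parent track ends and exactly two tracks begin in the next frame
   within 30 µm, each with 35–65% of the parent's last mass and jointly
   80–120% of it;
2. the parent's mean-phase trace matches a rising sigmoid (mitotic
   rounding);
3. both daughters' traces match a falling sigmoid (post-division
   flattening).

The matched filter is a logistic template (τ = 6 min) over a ±24 min window,
zero-mean and unit-norm; detections are local maxima of normalised
correlation above 0.7 with a fitted step height above 20 nm.  The window is
the widest that still fits inside a typical ~30 min pre-division rounding
period.  The furrow time t = 0 is the first frame in which the watershed
separates the daughters; time in mitosis is furrow minus the rising
midpoint, and post-division rounded time is the earliest falling midpoint
minus furrow.  Non-adherent cells do not change shape, so only criterion 1
applies and the two times are undefined.  Daughter 1 is the heavier daughter
at t = 0, making the signed Δm₀ non-negative.

## Partitioning statistics

Δm = 2|m_d1 − m_d2|/(m_d1 + m_d2) ∈ [0, 2].  Per event, Δm₀ is the signed
asymmetry at t = 0 and r is the ordinary-least-squares slope of signed Δm
over the first 60 min after the furrow (the span the population heatmap
displays); events with fewer than three post-furrow frames are flagged and
excluded.  Heatmap rows are ordered by θ = atan2(r, Δm₀), descending, which
separates the four canonical behaviours (symmetric-stable,
asymmetric-decreasing, asymmetric-stable, symmetric-increasing) into
contiguous blocks.  Signed Δm is used for slopes and heatmaps, absolute Δm
for population means; both heatmap matrices are written.

Population curves: mean |Δm| vs time with s.e.m. over events per bin;
coefficient of variation (sd/mean) of mass in 10-min bins over −90..+90 min
around the furrow; binned growth rates (finite differences of track mass) vs
time and vs relative mass.  Empty bins are reported missing, never zero.

Condition comparisons use a two-tailed Welch t test (unequal variances,
Welch–Satterthwaite degrees of freedom) and an F test of a least-squares
line against a constant-only model, F = (SSE₀−SSE₁)/(SSE₁/(n−2)) with
p from F(1, n−2).  Both are written out explicitly and cross-checked in the
tests against scipy references to 1e-8.  No multiple-testing correction is
applied; per-condition raw p-values are reported.

## Numerical choices and degenerate inputs

- A perfect linear fit (SSE₁ ≤ 10⁻¹² SSE₀) reports p = 0; a constant
  response reports slope 0, p = 1.  Two constant equal samples give
  t = 0, p = 1.
- Zero pair mass, single-class training labels, non-finite pixels,
  overlapping scenario placements, out-of-frame footprints and OPD ≥ 2λ all
  raise with context (cell, frame, coordinates).
- All randomness — generator noise, training splits — flows from explicit
  seeds; identical inputs and seed give bit-identical movies and identical
  output checksums (recorded in the run manifest).

## Problem sizes used in the validation suite

Unit and property tests run on 64–120 px patches with one or two cells;
the division-detector suite uses 50 division movies plus 50 division-free
movies (50 frames, 96×96 px); the population-asymmetry cohort uses 500
single-division movies (9 frames, 64×64 px) with daughter fraction
f ~ N(0.5, 0.03133) truncated to (0.01, 0.99), whose half-normal population
mean of |Δm| is 4σ√(2/π) ≈ 10%.  These sizes were chosen as the smallest
that leave discretization and sampling error well inside each test's
tolerance.

## Known limitations

- Watershed assigns each pixel of the daughter-pair overlap to exactly one
  side of the saddle, shrinking measured |Δm| by ~4–5% relative for touching
  lobes; the cohort mean therefore reads ≈ 9.1% where the programmed
  population value is 10.0%.
- The unwrap classifier is trained on the generator's morphology; real
  instruments would need retraining on annotated frames (the interface
  accepts any feature-stack/label pairs).
- Otsu-based marker selection assumes cells are bright against a dark,
  near-zero background; dense confluent fields (>≈50%) would merge
  foreground components and degrade marker selection.
- No gap closing: a single missed segmentation splits a track and can hide a
  division that straddles the gap.
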