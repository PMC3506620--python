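# Methods

This note documents the models, parameters, numerical conventions, and design
choices behind `choromorph`, in the spirit of a package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Coordinate system and calibration

Volumes are indexed `(a_scan, b_scan, depth)`. The standard macular cube is
512 A-scans × 128 B-scans over a 6 × 6 mm grid with ~2 mm of depth sampled at
1024 points, giving anisometric pitches of 6000/512 = 11.72 µm (fast axis),
6000/128 = 46.88 µm (slow axis), and 2000/1024 ≈ 1.95 µm (axial). All
quantification happens on this native grid with micron-space conversions;
GUI display rasters (e.g. a square 644 × 644 rendering) are treated as a
viewer resampling and are deliberately not emulated — when coordinates *are*
picked on a magnified display, `map_magnified_coords` scales them back by
`original/magnified` per axis. Axial sampling of ~1.95 µm per voxel makes a
"2 µm-thick" C-scan approximately one voxel, which is why slab extraction
interpolates with fractional depths throughout.

## 2. The synthetic phantom

### What it emulates

Each phantom eye renders, along depth: a dim pre-RPE region (30), a bright
RPE band (255, 16 µm thick) following a smooth surface, a choroid of known
thickness *T* split into three zones, and homogeneous sclera (120). The RPE
base surface is an elliptic paraboloid, `rpe_curvature_um` (default 100 µm,
sampled U(50, 150) in cohorts) deeper at the scan center than at the corners.
A low-order polynomial dome was chosen deliberately: it is representable by
the surface-fitting stage, so segmentation error reflects the detector, not a
model-mismatch floor.

The three zones occupy fixed fractions (0.25, 0.35, 0.40) of *T* —
choriocapillaris, Sattler, Haller. Each zone contains straight, parallel,
hypo-reflective vessels (intensity 40 on stroma 180) with calibers drawn from
symmetric truncated normals: 50 ± 8 µm (inner), 100 ± 10 µm (middle),
215 ± 12 µm (outer), matching the reported in vivo averages (~50, ~100,
~215 µm). Eyes without a visible choriocapillaris (all reticular eyes, and
early-AMD eyes with probability 1 − 5/11) render middle-caliber vessels in
the innermost zone instead — the "larger channels resembling the middle
layer" appearance.

Target densities default to the full-scan per-layer in vivo averages:
(76.5, 83.6, 87.2)% for controls, (72.2, 80.3, 87.2)% for early AMD, and
(73.8, 80.0, 85.9)% for reticular eyes. The vessel/stroma intensities are a
free choice of the phantom (no stromal reflectance statistics are available);
they were set so that strict-threshold (65) binarization is the correct
classifier by construction and densities land in the observed 63.8–97.2%
range.

### Vessel geometry: constant-width ribbons

Vessels are rendered as **constant-width ribbons** — rectangular cross
sections with horizontal width equal to the drawn caliber and axial extent
capped per layer (30/60/50 µm defaults, and at most the zone minus stromal
margins) — rather than circular tubes. Two reasons:

1. A circular 215 µm tube does not fit axially inside the ~80 µm Haller zone
   of a 200 µm choroid; anatomically, large choroidal lumens are wide and
   flattened. Without an axial cap the generator enforces the literal rule
   that a zone thinner than one vessel diameter is rejected.
2. The horizontal chord of a circle equals its diameter only at the exact
   equator, so with ~2 µm slabs every ground-truth quantity would depend on
   sub-voxel slab placement. With ribbons, the en face chord equals the
   caliber at *every* depth inside the band, making ground-truth density and
   diameter analytic and placement-insensitive.

Within a layer all vessels share one orientation, drawn uniformly within
±15° of the slow-scan axis, with random stromal gaps scaled so expected
coverage matches the target density. Near-perpendicular orientation keeps
the horizontal caliper honest (sec 15° = 1.035, so the worst-case horizontal
widening is ~3.5%); a fully isotropic orientation distribution would make
the mean horizontal chord of a strip divergent (E[sec θ] → ∞) and the
horizontal-diameter protocol meaningless. One orientation per layer also
guarantees vessels never cross, so horizontal runs measure single lumens.

Ground truth records, per layer: the exact rendered coverage fraction of the
en face grid (identical at every depth inside the band, hence recomputable
from the label volume), the mean drawn caliber, the band's depth interval,
and its center — the depth a perfectly informed reader would place the
C-scan at.

### Speckle

Multiplicative log-normal speckle, `I' = clip(I·exp(N(−σ²/2, σ²)))` with
σ = 0.1 by default. At the rendered contrast (vessel 40, stroma 180,
threshold 65) misclassification under this noise is negligible, which is the
point: the recovery tests then measure geometric pipeline error, not an
arbitrary noise battle. σ is a configurable knob for robustness studies.

### What the phantom does *not* model

No retinal layers above the RPE, no drusen deformation of the band, no
depth-dependent signal attenuation or shadowing under vessels, no vessel
branching/tortuosity, no segmentation artifact from pathology, and no
spatial inhomogeneity of vessel density across the macula. Passing recovery
tests therefore demonstrate that the measurement chain is unbiased and
sharp under the stated geometry — not that it is robust to every real-world
confound (attenuation and pathology-induced segmentation error being the
important ones).

### Cohorts

Cohort sampling draws, per group: age from the reported mean ± SD (61 ± 10.7
control, 76.7 ± 9 early AMD, 82.6 ± 7 reticular, 84.3 ± 7.6 advanced;
clamped to 41–97), gender from the reported proportions (50%, 36%, 83%, 80%
female), choroidal thickness from 207 ± 42.5 / 228.6 ± 58.4 / 163.4 ± 68.5 /
179 ± 99.4 µm, and choriocapillaris presence (certain / Bernoulli(5/11) /
absent / absent). Thickness draws are clamped to 130–380 µm: below ~130 µm
three renderable vessel bands no longer fit, and the upper clamp keeps the
choroid inside the axial field of view. The advanced-reticular SD (99.4) in
particular would otherwise produce non-physical draws.

## 3. RPE surface segmentation

Per A-scan the axially Gaussian-smoothed (σ = 1.5 voxels) profile is
maximized to find the band, the tissue level just below the band is sampled
immediately past the first large drop (below 0.85 × peak), and the posterior
edge is located where the profile falls through the midpoint between peak
and sub-band level, with linear interpolation between voxels. The half-height
crossing of a blurred step sits half a voxel above the first sub-band voxel,
so +0.5 lands the estimate on the RPE base. The per-column map is then
regularized by a total-degree-4 least-squares polynomial surface (normalized
coordinates for conditioning); the RMS residual in microns is reported as a
quality indicator. Validated against phantom ground truth, the fitted
surface is accurate to well under one voxel with a small (+~0.4 voxel) bias
from asymmetric structure below the edge.

## 4. C-scan extraction and layer placement

`extract_slab` averages linearly interpolated intensity over
`[r + d, r + d + t]` (default t = 2 µm, 5 depth samples), raising a
descriptive error if the window exits the volume anywhere. Layer placement
defaults are a documented convention of this package (the emulated protocol
placed slices manually with cross-sectional guidance): choriocapillaris at
15 µm below the RPE base — deep enough that a one-voxel slab samples the
interior of the band rather than its partial-volume edge — Sattler at 40%
and Haller at 75% of the measured choroidal thickness. Explicit per-eye
offsets (including ground-truth band centers on synthetic data) override the
defaults verbatim. For eyes without a visible choriocapillaris the same
innermost offset is used: it is the "most representative scan immediately
beneath the RPE", and in phantoms of such eyes that depth intersects the
middle-caliber vessels rendered there.

## 5. Binarization, density, and region selection

Thresholding is inclusive (`intensity ≤ θ` is vessel), strict default
θ = 65, loose θ = 110 retained as an option; on grayscale slabs the R=G=B
rule collapses to one comparison. Density is a pixel fraction; micron-space
regions convert to pixel windows with a pinned convention — origin at the
floor pixel, window `ceil(size/pitch)` per axis, 0-based, rows = B-scans —
so a 500 × 500 µm region is 43 × 11 px at standard pitches.

Automatic region selection ("representative area with visible vasculature")
scores non-overlapping candidate tiles by mean absolute horizontal gradient
(vessel/stroma alternation), discards tiles below half the best score, and
returns the tile with the **median** score. Two deliberate choices: a raw
intensity-variance criterion is maximized where the vessel fraction is
nearest 50%, so at realistic 75–90% densities it would systematically select
the *least* representative window and bias regional density downward; and
taking the maximum-alternation window has the same flaw in milder form
(most alternation = most gaps). The median-of-visible rule is unbiased with
respect to local coverage fluctuations. A manual origin is honored verbatim.

## 6. Diameter measurement

Diameters are measured on the binarized mask (edges are then unambiguous;
the emulated protocol picked edges visually). `measure_diameter` returns the
horizontal run of contiguous vessel pixels through a seed. For per-image
summaries, `component_diameters` detects vessels as 8-connected components,
collects runs over the central half of B-scan rows, drops runs touching the
lateral boundary (vessels cut off by the scan edge are not fully "visible"),
and takes each component's median run — robust to occasional pixel bridging
between neighbors. `summarize_diameters` then applies the protocol's rules:
the standard scheme averages the largest and smallest vessel (≥ 2 required);
the five-measurement scheme for superficial layers without choriocapillaris
averages min/Q1/median/Q3/max representatives (≥ 5 required). Both schemes
are unbiased for the symmetric caliber distributions of the phantom.

## 7. Choroidal thickness

The choroid–sclera junction is the deepest sustained downward step below the
RPE: the B-scan is laterally box-filtered (31 columns) so vessel texture
averages toward the layer mean, a two-sided moving-mean difference (3 voxels
each side) is computed along depth, the deepest position exceeding 25 gray
levels of drop (at least 30 µm below the RPE, excluding the RPE edge itself)
is taken, refined to the local step minimum, and the profile is
median-filtered across columns. Thickness is `(CSJ − RPE base) × axial
pitch` at the central A-scan of the central B-scan (the foveal column of a
fovea-centered cube; the emulated protocol used separate high-definition
raster scans, which a single-volume pipeline approximates by the central
B-scan). The phantom keeps a 10 µm stromal margin between the outer vessel
band and the sclera precisely so this junction remains a clean step.

## 8. Choriocapillaris visibility

The qualitative "granular layer present" grading is replaced by a spectral
surrogate: the fraction of non-DC spatial power (fast axis, pitch-aware
frequencies) above 12 cycles/mm. The ~65 µm vessel+gap period of an intact
choriocapillaris has its fundamental near 15 cycles/mm (above the cutoff);
the ~130 µm period of middle-caliber vessels falls near 8 (below). The
decision threshold 0.66 was calibrated once on dedicated synthetic
calibration cohorts — intact-choriocapillaris slabs scored ≈ 0.91, absent
≈ 0.41, and the midpoint was frozen — and is then held out from all tests.
This surrogate is validated only on phantoms; on real data the printed
visibility counts are used directly as inputs to the Fisher test.

## 9. Statistics

- **ANOVA**: classical one-way F. If the between-group sum of squares is
  exactly zero, F = 0 and p = 1 by convention. Standard errors of group
  means use the pooled MSE.
- **ANCOVA**: OLS on group indicators plus covariates — model 1 adjusts for
  choroidal thickness, model 2 for age and gender (age linear, gender as a
  binary indicator; the simplest models consistent with "adjusting for").
  The omnibus statistic is the partial F for the group factor. Adjusted
  means are predictions at the covariate grand means (indicator covariates
  at observed proportions) with model-based standard errors — the standard
  ANCOVA presentation of "adjusted" rows. An empty covariate set reduces
  exactly to the one-way ANOVA. Rank-deficient designs raise an error naming
  the collinear columns.
- **Bonferroni**: pairwise p × number of pairs, capped at 1; pairwise
  comparisons are computed only when the omnibus p < 0.05.
- **Fisher r × c**: exact, two-sided by probability ordering — the sum of
  probabilities of all margin-preserving tables no more probable than the
  observed one, by exhaustive enumeration (log-gamma arithmetic; ties
  accepted within a 1e-9 relative band). Appropriate because the tables here
  are small. A zero row/column margin returns p = 1 with a warning.
- **Calibration**: `anova_type1_rate` simulates null cohorts at the observed
  group sizes (14, 11, 23, 10) and reports the empirical type-I error at
  α = 0.05.

## 10. Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; rerunning any pipeline or script with the same
seed is byte-identical. Unit tests run on a quarter-size cube (256 × 64 ×
512 over 3 mm) that preserves all three pixel pitches, so pitch-dependent
behavior is identical to full size. End-to-end recovery runs use the full
512 × 128 × 1024 geometry with 5 eyes per group (20 eyes), a size at which
cohort-level recovery statistics are stable; the null-calibration uses 1000
replicate cohorts. The acceptance script completes in a few minutes on one
CPU.

## 11. Known limitations

- Layer-offset fractions (40% / 75%) and the 15 µm choriocapillaris offset
  are conventions, not measurements; real protocols place slices under
  visual guidance, and the package exposes both manual and ground-truth
  overrides for that reason.
- The visibility surrogate and its threshold are phantom-calibrated;
  applying them to real scans would require recalibration against human
  grading.
- Regional density on a single 500 × 500 µm window has irreducible sampling
  variance at large vessel calibers (a window spans only ~2 Haller vessel
  periods); recovery guarantees are therefore stated for cohort-level means.
- The thickness caliper assumes a detectable choroid–sclera contrast step;
  eyes with very low scleral contrast would need the threshold parameters
  adjusted.
- One eye per patient is assumed throughout; no clustered/mixed-effects
  modeling is provided.
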