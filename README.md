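# choromorph

Quantitative morphometry of the **choroidal vasculature** from en face OCT,
for retina researchers who want reproducible, scriptable versions of the
measurements usually made by hand in device software: vessel density and
caliber of the three choroidal vascular layers, choroidal thickness, and the
group statistics used to compare clinical cohorts (controls with epiretinal
membrane, early age-related macular degeneration, and reticular pseudodrusen).

## What it computes

Starting from a macular-cube volume *V(x, y, z)* (512 A-scans × 128 B-scans
over a 6 × 6 mm grid, ~2 mm of depth):

- **RPE-contoured C-scans.** The RPE base surface *r(x, y)* is segmented
  (per-A-scan bright-band edge detection regularized by a least-squares 2-D
  polynomial), and 2 µm-thick en face slabs are extracted at depth *r + d*
  for the choriocapillaris, Sattler's (middle), and Haller's (outer) layers,
  so each slab follows the patient's RPE curvature.
- **Vessel density.** Pixels with intensity ≤ θ are vessel (strict θ = 65 of
  255; loose θ = 110 available); density = vessel fraction over the full scan
  or over a selected 500 × 500 µm region,
  ρ = |{p : I(p) ≤ θ}| / N.
- **Vessel diameter.** Horizontal run length through the lumen in pixels,
  converted with the anisometric pitch: 6000/512 = 11.7 µm per pixel
  horizontally, 6000/128 = 47 µm vertically. Per-image summaries follow the
  two-measurement rule (mean of largest and smallest visible vessel) or the
  five-measurement rule for superficial layers without a choriocapillaris.
- **Choroidal thickness.** Caliper from the RPE base to the choroid–sclera
  junction at the foveal column.
- **Choriocapillaris visibility.** An automated surrogate for the qualitative
  "granular layer" grading: the fraction of en face spectral power above
  12 cycles/mm, thresholded at a calibrated cutoff.
- **Cohort statistics.** One-way ANOVA; ANCOVA adjusting for choroidal
  thickness (model 1) or age and gender (model 2) with adjusted group means
  at the covariate grand means; Bonferroni pairwise p-values when the omnibus
  test is significant; and an exact Fisher r × c test (exhaustive enumeration
  over fixed margins) for visibility counts.

Because no imaging data ships with studies of this kind, the package includes
a first-class **synthetic phantom generator**: full-geometry OCT cubes with a
curved RPE, three stacked vascular layers of known caliber and density,
multiplicative speckle, and voxel-level ground truth — so the entire pipeline
is validated end to end against known answers.

## Worked example

```python
from choromorph import (
    default_eye_params, generate_volume, segment_rpe, segment_csj,
    measure_thickness, locate_layers, extract_slab, binarize, vessel_density,
    select_region, component_diameters, summarize_diameters,
    choriocapillaris_visibility,
)

params = default_eye_params("control", seed=42)
volume, truth = generate_volume(params)
surface = segment_rpe(volume)
csj = segment_csj(volume, surface)
thickness = measure_thickness(volume, surface, csj)
print(f"choroidal thickness: {thickness.thickness_um:.1f} um "
      f"(ground truth {truth.choroid_thickness_um:.1f} um)")

offsets = locate_layers(surface, thickness.thickness_um)
for layer, offset in zip(("choriocapillaris", "Sattler", "Haller"), offsets):
    slab = extract_slab(volume, surface, offset)
    mask = binarize(slab, threshold=65)
    full = vessel_density(mask)
    origin = select_region(slab, (500.0, 500.0))
    region = vessel_density(mask, origin, (500.0, 500.0))
    diam_px, diam_um = summarize_diameters(component_diameters(mask), "standard")
    print(f"{layer:16s} offset {offset:5.1f} um | density full {100*full.density:.1f}% "
          f"region {100*region.density:.1f}% | diameter {diam_px:.2f} px = {diam_um:.0f} um")

visible, score = choriocapillaris_visibility(extract_slab(volume, surface, offsets[0]))
print(f"choriocapillaris visible: {visible} (granularity score {score:.2f})")
```

prints

```
choroidal thickness: 205.4 um (ground truth 207.0 um)
choriocapillaris offset  15.0 um | density full 76.4% region 76.5% | diameter 4.50 px = 53 um
Sattler          offset  82.1 um | density full 84.4% region 86.9% | diameter 8.50 px = 100 um
Haller           offset 154.0 um | density full 86.9% region 86.7% | diameter 18.50 px = 217 um
choriocapillaris visible: True (granularity score 0.92)
```

The measured thickness is within 2 µm of the phantom's ground truth; the
densities sit in the typical in vivo ranges (inner ~76%, middle ~84%, outer
~87%); and the recovered calibers (~50, ~100, ~215 µm) match the specified
vessel sizes of the three layers. A one-command demo of the whole study —
generation, analysis, statistics — is available as `choromorph run`
(see `choromorph --help` for the `generate` / `analyze` / `report`
subcommands).

## Layout

- `src/choromorph/synthetic.py` — phantom generator with ground truth
- `src/choromorph/volume_io.py` — TIFF/PNG/JSON-sidecar readers and writers
- `src/choromorph/rpe.py` — RPE base surface segmentation
- `src/choromorph/enface.py` — C-scan extraction, layer placement, visibility
- `src/choromorph/vessels.py` — binarization, density, diameters, calibration
- `src/choromorph/thickness.py` — choroid–sclera junction and thickness
- `src/choromorph/stats.py` — ANOVA / ANCOVA / Bonferroni / exact Fisher
- `src/choromorph/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, parameters, and design choices in detail
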