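# orgprof

Automated segmentation and quantitative analysis of secretory organelles
in multi-channel fluorescence images.

Secretory organelles — e.g. Weibel-Palade bodies (WPBs), the elongated
VWF-storage organelles of endothelial cells — vary widely in number, size
and shape from cell to cell, so phenotyping them requires measuring
thousands of organelles on a per-cell basis rather than eyeballing a few.
`orgprof` provides that measurement chain for confluent monolayers imaged
with a nuclear stain, a junctional membrane stain (e.g. VE-cadherin), an
organelle cargo stain (e.g. VWF), and optionally a secondary content
stain (e.g. Rab27A):

1. **Segment** nuclei (smoothed + thresholded primary objects), cells
   (seeded propagation from the nuclei on the membrane channel, step cost
   `sqrt(ΔI² + λ²s²)`), membranes (per-cell boundary band), and
   organelles (white top-hat speckle/rod enhancement + threshold).
2. **Measure** per organelle: area; eccentricity
   `e = sqrt(1 − (b/a)²)` of the moment-equivalent ellipse; length as the
   maximum Feret diameter (largest caliper distance across the convex
   hull of the pixel centers); distance of the centroid to the nucleus
   (`d_nuc`) and to the cell edge (`d_mem`); and the relative position
   `100·d_nuc/(d_nuc+d_mem)` (0% at the nucleus, 100% at the cell edge).
3. **Relate** organelles to their parent cell and aggregate per cell and
   per image.
4. **Quantify content** (optional): expand organelle labels by 2 px, and
   per cell measure the secondary channel inside vs outside the
   organelles, reporting `corrected = mean_in − mean_out` in arbitrary
   intensity units.

A fully ground-truthed synthetic-field generator (tessellated cells,
elliptical nuclei, membrane ridges, capsule-shaped organelles with
closed-form moment eccentricity, two-level content channel, PSF blur +
noise) makes every stage testable by parameter recovery without any
external data.  See `docs/methods.md` for the model details and
conventions.

## Worked example

Generate a synthetic monolayer (12 cells, 6 organelles per cell drawn
from the elongated phenotype preset: length 1.38 ± 0.21 µm, eccentricity
target 0.78), run the organelle-profiling pass, and compare against a
short/round phenotype field (1.10 ± 0.27 µm, 0.63):

```sh
orgprof synth --preset group1 --n-images 1 --seed 3 --out fields
orgprof run-op --out results fields/*.tif
head -2 results/per_image.csv
```

```
image_id,cell_count,organelle_count,organelles_assigned,organelles_unassigned,mean_organelles_per_cell,mean_length_um,mean_eccentricity,mean_rel_dist_pct
group1_000,12,72,72,0,6.0,1.3625861832960606,0.7663297343923329,39.20000075274653
```

All 12 cells and 72/72 organelles are recovered; the per-cell mean
organelle length (1.36 µm) and eccentricity (0.77) recover the generator
inputs.  `results/` also contains `per_cell.csv`, `per_organelle.csv`, a
QC overlay PNG with numbered cell outlines, the resolved configuration,
and a QC log of unassigned organelles and multi-nucleus cells.

```sh
orgprof synth --preset group3 --n-images 1 --seed 3 --out fields3
orgprof run-op --out results3 fields3/*.tif
orgprof report --a results/per_cell.csv --b results3/per_cell.csv
```

```
organelle_count: degenerate p=1  A mean=6 (n=12)  B mean=6 (n=12)
mean_length_um: welch p=5.14e-06  A mean=1.363 (n=12)  B mean=1.086 (n=12)
mean_eccentricity: welch p=7.11e-06  A mean=0.7663 (n=12)  B mean=0.6029 (n=12)
mean_rel_dist_pct: welch p=0.858  A mean=39.2 (n=12)  B mean=39.87 (n=12)
```

The two phenotypes separate decisively on organelle length and
eccentricity (both groups were generated with 6 organelles per cell and
the same radial placement, so counts and relative distance do not
differ).  For content quantification, `orgprof run-ocp` adds per-cell
`content_mean_in`, `content_mean_out` and `content_corrected` columns
from a 4th channel (`--preset content` generates a matching field with
levels 0.08 in / 0.05 out).

The same functionality is available as a library:

```python
from orgprof import PipelineConfig, process_image
from orgprof.synth import group1_wpb_params, generate_field

image, truth = generate_field(group1_wpb_params(rng_seed=3))
result = process_image(image, PipelineConfig())
print(result.per_cell[["cell_label", "organelle_count", "mean_length_um"]])
```

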