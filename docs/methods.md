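# Methods

`orgprof` quantifies secretory organelles in multi-channel fluorescence
images of cell monolayers: it segments nuclei, cells, membranes and
organelles, measures per-organelle size, shape and intracellular position,
aggregates per cell, and optionally quantifies a secondary marker inside
vs outside the organelles.  This note records the model behind each
stage, the parameters that matter, what the synthetic validation fields
do and do not emulate, and the numerical conventions the package commits
to.

## Segmentation model

**Object hierarchy.**  Nuclei are *primary* objects: the nuclei channel
is Gaussian-smoothed (default σ = 2 px), thresholded (Otsu by default,
with a multiplicative correction factor and clip bounds), hole-filled,
optionally declumped, connected-component labeled (8-connectivity), and
size-filtered by equivalent diameter.  Cells are *secondary* objects
grown from the nucleus seeds; membranes are *tertiary* objects derived
from the cells; organelles are a second primary pass on the enhanced
organelle channel.

**Seeded propagation.**  Each foreground pixel joins the nucleus seed
that reaches it with minimal accumulated cost, where a step between
8-neighbors p → q costs

    c(p, q) = sqrt((I(p) − I(q))² + λ² s²),

with I the smoothed membrane intensity, s the Euclidean step length (1 or
√2) and λ ≥ 0 a regularization weight (default 0.05).  Small λ makes
boundaries hug membrane ridges (the intensity-difference term dominates);
large λ approaches a Voronoi partition of the seeds in the chamfer
metric.  The solver is a vectorized label-correcting relaxation iterated
to its fixed point, which is the exact lexicographic (cost, seed-label)
minimum over all paths — identical, tie rule included, to a Dijkstra
solution; ties in accumulated cost go to the lower seed label, and seed
pixels always keep their own label.  The test suite verifies
pixel-for-pixel agreement against an independent heap-based Dijkstra
oracle on random guides.  With a constant guide the partition is a
chamfer-metric Voronoi diagram; it can deviate from the true Euclidean
diagram in a narrow band around bisectors (8-connected chamfer error
≈ 4%), which the tests account for by asserting Voronoi agreement only at
pixels with a clear distance margin.

**Foreground.**  Confluent monolayers tessellate the full field, so the
default propagation foreground is every pixel.  For sparse cultures an
Otsu-thresholded foreground on the smoothed membrane channel can be
selected (`cell_foreground: threshold`); this is approximate, since a
junctional stain is not a cytoplasmic fill.

**Declumping.**  Touching primary objects can be split by a watershed on
the Gaussian-smoothed distance transform, seeded at local maxima at least
d_min apart (d_min = the lower diameter bound).  Shape-based declumping
only; intensity-based splitting is an extension point.  Off by default
for both nuclei and organelles — in the synthetic validation regime
objects are separated, and on real data declumping should be a deliberate
choice because it trades under- for over-segmentation.

**Membrane band.**  Per cell, the membrane is the set of cell pixels
within `width_px` (default 3) of the cell's boundary — equivalently, the
cell minus its Euclidean erosion.  Interfaces with neighboring cells and
the image edge both count as boundary; the band keeps the cell's label.

**Organelle enhancement.**  The organelle channel is contrast-stretched
to [0, 1] and passed through two white top-hats: a disk of radius 5 px
(speckles) and the pixel-wise maximum over line structuring elements of
length 11 px at 15° steps (rods of any orientation).  The final enhanced
image is the pixel-wise maximum of the two — it preserves both round and
elongated organelle responses, stays ≤ the input everywhere (top-hat
property), and suppresses broad background so close-packed organelles
separate before thresholding.  Speckle radius should be at least half the
expected organelle width; line length at least the organelle length.
Multi-angle linear top-hats were chosen over Hessian tubeness filters:
parameter-light and adequate at organelle scale.

**Border policy.**  Objects touching the image border are kept by
default (tile scans would otherwise bias per-image counts); discard is
configurable per object class.

## Morphometry

All measurements use (row, col) coordinates with pixel centers at integer
positions, and an explicit pixel size in µm per pixel — there is no
silent default calibration.  Raw integer images are normalized by their
dtype maximum on load so thresholds are bit-depth independent.

* **Area**: pixel count × pixel_size².
* **Eccentricity**: e = sqrt(1 − (b/a)²) of the ellipse with the same
  second central moments (0 = circle, → 1 = line).  Note e is
  ill-conditioned near 0: on objects smaller than ~100 px, rasterization
  jitter of <1% in the axis ratio can move e by ~0.1 near round.  The
  axis ratio b/a is the well-conditioned alternative for near-round
  objects.
* **Maximum Feret diameter** (reported as organelle length): the maximum
  pairwise distance between convex-hull vertices of the object's *pixel
  centers* (all-pairs over hull vertices; exact all-pairs fallback for
  collinear objects).  Pixel-center convention: a 1 × N segment has Feret
  (N − 1) px; conventions using pixel corners differ by ~1 px.  The
  synthetic ground truth uses the same convention, and an all-pairs
  oracle over every pixel verifies hull equivalence exactly.
* **Intensity**: mean and integrated intensity per object, in the
  channel's normalized arbitrary units (A.U.).
* **Distances**: from the organelle *centroid* (not its nearest edge —
  this keeps rod length out of the position measurement) to (a) the
  nearest pixel of its cell's nucleus (`d_nuc`, 0 inside the nucleus) and
  (b) the nearest pixel of the cell's outer boundary (`d_mem`).  Both
  come from distance transforms computed per cell in isolation, so a
  neighboring cell's nucleus can never shadow the assigned one.  Cells
  with zero or multiple nuclei are flagged and their organelles' distances
  left missing.
* **Relative distance**: 100 · d_nuc / (d_nuc + d_mem) — 0% at the
  nucleus edge, 100% at the cell edge, undefined (missing) when both are
  zero.

## Parent–child relation and aggregation

Each organelle is assigned to the cell under its centroid pixel; if the
centroid lands on background, to the cell with maximal pixel overlap
(ties to the lower label); with no overlap it stays unassigned (parent
0), excluded from per-cell statistics but always counted in the QC log.
Reporting is two-level: per-cell summaries (count, mean length, mean
eccentricity, mean relative distance; means missing for empty cells) —
the default statistical unit for group comparisons — and a pooled
per-organelle table for single-organelle analyses.

## Content quantification

Organelle labels are expanded by 2 px (configurable) before masking, so a
membrane-bound marker sitting just outside the cargo stain is captured.
Per cell, *inside* = expanded-organelle pixels ∩ cell, *outside* = cell ∖
expanded organelles, and

    corrected = mean_in − mean_out,

a difference of means (not a ratio), which may legitimately be negative.
Label expansion assigns each background pixel within the radius to its
nearest object, with exact distance ties (compared on integer squared
distances) going to the lower label; expansions never overwrite or merge
labels, and expansion crossing a cell border is clipped to the owning
cell.

Variants: the outside mask can exclude the nucleus (off by default — the
plain cytoplasm-minus-organelles mask is the primary contract), or be
restricted to a local ring of configurable width around the organelles,
which is less sensitive to intensity gradients across the cell.  A mode
that re-identifies thresholded "signal objects" inside the masks before
measuring is deliberately *not* the default: it would add a threshold
dependence with no principled setting; mask means are parameter-free.

Content intensities are measured on the raw (dtype-normalized) channel.
Full-range rescaling is applied only for QC display — rescaling before
measurement would make A.U. values incomparable across images.

**Blur bias.**  Optical blur moves intensity across the in/out mask
boundary: a Gaussian PSF of width σ removes ≈ 0.4 σ P Δ of signal from
the inside mask (P = mask perimeter, Δ = true contrast), biasing
`corrected` low by roughly 0.4 σ P/A relative (A = mask area) — about 7%
at σ = 0.5 px for the default synthetic organelle geometry.  The content
validation preset therefore renders the content step sharp (no PSF on
that scenario), isolating the masking/correction arithmetic; the bias
formula above describes what to expect on blurred data.  Expanding the
mask further does not recover the loss (it dilutes the mean instead);
saturation of `mean_in` under extra expansion holds only when the
organelle is large relative to the expansion increment and the blur is
comparable to it.

## Synthetic validation fields

The generator emulates a confluent monolayer: Poisson-disk-sampled cell
centers tessellated by nearest-center assignment; one elliptical nucleus
per cell (clipped to the cell interior); a membrane ridge along every
cell-cell border; organelles as anti-aliased capsules (rectangle plus
semicircular caps — the "cigar" morphology of secretory rods) placed at a
sampled fraction along the ray from the cell center to its boundary, with
pairwise overlap rejected; an optional content channel at level µ_in on
the organelles plus a 2-px halo and µ_out elsewhere in the cell.  All
channels are rendered in [0, 1], blurred by a Gaussian PSF and corrupted
with additive Gaussian noise clipped at zero.  Ground truth (cell map,
nucleus parameters, per-organelle center, orientation, length, width,
eccentricity, radial fraction) is recorded before blur and noise.

The capsule's moment eccentricity has a closed form: with body
half-length a = (L − w)/2 and cap radius r = w/2,

    A  = 4ar + πr²
    Ix = (4/3)a³r + πa²r² + (8/3)ar³ + πr⁴/4
    Iy = (4/3)ar³ + πr⁴/4
    e  = sqrt(1 − Iy/Ix),

verified against supersampled numerical moments.  Group presets specify a
target eccentricity; the generator inverts this closed form at the mean
length to obtain the capsule width (per-organelle width is capped at
0.95 × length so short draws remain valid capsules, and the stored truth
always uses the realized length/width pair).  Organelle length is drawn
once per organelle from a truncated normal and only the placement pose is
retried, so packing rejection cannot bias the realized length
distribution; a length is redrawn (bounded) only after exhausting every
pose, and an infeasible load raises after bounded retries.

**Default study conditions** (chosen once): 256 × 256 px at 0.1 µm/px,
12 cells, nucleus semi-axes (1.6, 1.1) µm, membrane ridge 2 px, 6
organelles per cell, radial fraction uniform on (0.35, 0.9) — the lower
bound keeps organelle centers clear of the nucleus so radial position
recovery is not dominated by zero-distance ties — PSF σ = 0.5 px, noise
σ = 0.01.  The geometry is a scaled-down monolayer: cells (~7 µm across)
and nuclei are several-fold smaller than real endothelial cells, while
organelle size (length ~1.1–1.5 µm) and the pixel pitch are realistic, so
per-organelle measurements run at true sampling density while whole
fields stay small.  Group presets use published phenotype parameters as
simulation inputs: length 1.38 ± 0.21 µm / eccentricity 0.78 vs
1.10 ± 0.27 µm / 0.63 for the two donor phenotype groups, 1.54 ± 0.17 µm
/ 0.87 vs 1.17 ± 0.18 µm / 0.76 for the vehicle vs microtubule-disruption
conditions, and content levels (0.08, 0.05) vs equal (0.065, 0.065) for
the organelle-bound vs ER-like marker scenarios.

**What passing tests do and do not show.**  The fields have uniform
staining, ideal tessellation, no illumination gradients, no
autofluorescence, no out-of-focus light, and additive Gaussian noise only
(no Poisson shot noise — negligible at these intensity scales for the
properties under test).  Organelles never overlap unless the `crowded`
mode (`allow_overlap`) is enabled.  Recovery on these fields validates
the measurement chain — segmentation, geometry, relation, correction
arithmetic — not robustness to real-microscopy artifacts; thresholds and
filter sizes always need re-tuning per real dataset.

## Numerical conventions and edge cases

* Ties are deterministic everywhere: propagation cost ties and expansion
  distance ties go to the lower label; labels are renumbered 1..N in
  raster order of each object's first pixel.  Same input + config ⇒
  byte-identical CSV output.
* A constant image rescales to all zeros; thresholding an all-zero image
  yields an empty mask; zero objects is a valid result, not an error.
* Relative distance is missing (NaN, excluded from aggregation) when both
  distances are zero; per-cell means are missing for cells without
  organelles; empty masks yield missing content means.
* Euclidean label expansion does not compose exactly on the integer
  lattice: expanding by a then b can fall one pixel short of expanding by
  a + b (no intermediate lattice point), so only inclusion with 1-px
  slack holds.
* Rasterized Feret carries ~1 px of tip quantization; orientation spread
  stays below 5% of length only for rods ≳ 16 px.
* The distance transforms behind `d_nuc`/`d_mem` are sampled at the
  (float) centroid by bilinear interpolation — accurate to about half a
  pixel.

## Known limitations

2D only (z-stacks are max-projected on load); no machine-learned
segmentation; no illumination correction or deconvolution; the
thresholded "signal objects" content mode is exposed but not validated
against ground truth; hypothesis tests (Welch / Mann-Whitney) are a thin
reporting convenience, not a statistical framework.
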