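# Methods

`invadopipe` reimplements, as one reusable pipeline, the image-analysis and
proteomics post-processing used to isolate invadosome rosettes by laser
capture microdissection (LCM) and to characterize their proteome by SILAC
mass spectrometry. This note describes each stage's model and assumptions,
the parameters that matter, the synthetic data the tests run on, and the
numerical choices that were genuinely open.

## Segmentation of invadosome rosettes

Invadosome rosettes in Src-transformed fibroblasts are F-actin rings, 5–7 µm
in diameter, imaged in the red (LifeAct-mRuby) channel. The segmentation
chain is an ImageJ-style particle analysis applied per field, in this fixed
order:

1. **Channel split** — only the red channel of an RGB acquisition is kept.
2. **Median filter**, disk radius 2 px (reflect edge padding) — removes
   shot noise without displacing the thin ring wall.
3. **Rolling-ball background subtraction**, radius 20 px — the background
   is the surface swept by a ball rolling under the intensity landscape,
   computed exactly as a grayscale opening (erosion then dilation) with a
   spherical structuring element. No image-shrinking approximation is used;
   the estimate never exceeds the image, so a flat field subtracts to zero.
4. **Automated threshold** — IsoData by default (Otsu selectable). IsoData
   is implemented as Ridler–Calvard iterative intermeans,
   t ← (μ_below + μ_above)/2, **initialized at the midpoint of the occupied
   intensity range**. The initialization is load-bearing: on fluorescence
   fields where foreground covers well under 1% of pixels the intermeans
   update has several fixed points, and iterations started low converge to a
   spurious threshold inside the background noise. Midrange initialization
   converges to the between-class fixed point. The mask keeps pixels
   strictly above the threshold; a constant image raises a
   degenerate-histogram error, which the full chain treats as an empty field.
5. **Closing (disk radius 1 px) + hole filling**, iterated to a fixed point
   so the operator is exactly idempotent. Closing bridges 1-px breaks in
   the ring wall; hole filling turns the annulus into a solid disk, which is
   what makes the circularity filter meaningful.
6. **Connected components** (8-connected by default) with calibrated shape
   descriptors, then **filtering**: area ≥ 10 µm² and circularity within
   [0.35, 1], both bounds inclusive. Rosettes become compact ~20–40 µm²
   blobs and pass; stress fibers (long thin bars) and noise specks fail.

### Perimeter and circularity

Circularity is min(1, 4π·A/P²), clamped to absorb discretization overshoot.
Area is exact (pixel count × pixel size²). Perimeter uses a documented
estimator: the outer inter-pixel ("crack") boundary is traced (vertices at
pixel corners), collinear runs are merged, and every corner adjacent to a
unit-length run — a staircase step — is cut by routing the polygon through
the midpoints of both adjacent segments; corners between two longer runs
are kept. The midpoint cut is exact on digital straight lines of any slope,
so:

- an axis-aligned w×h rectangle keeps its full crack perimeter 2(w+h):
  the 2×20 px bar measures P = 44 px, circularity 4π·40/44² ≈ 0.260, and is
  correctly rejected by the 0.35 floor;
- digitized disks of radius ≥ 10 px measure circularity 0.94–0.98, safely
  inside the filter.

A raw crack perimeter would push disk circularity to ~0.6 (breaking the
filter's intent), and a pixel-center polygon would overestimate the
circularity of thin bars; this estimator is the one choice we found that is
faithful to both object classes at the published cut-offs.

## Microdissection planning

The microdissector cuts polygons specified in stage micrometres. Image
coordinates are 0-based with a pixel-centre convention — pixel (0, 0) maps
exactly to the field's stage origin — while dissection polygons use
pixel-corner vertices (the traced boundary), so a 10×10 px region whose
first pixel is (100, 100) exports corners (100, 100)…(110, 110) µm at
1 µm/px. Stage y grows downward by default; instruments with an upward y
axis set `y_axis_flip`, which mirrors y about the field. Field tiling
places centres exactly one field width/height apart (row-major; serpentine
optional), so adjacent fields abut without gap or overlap.

The instrument's native element-list format is proprietary, so the export
is an open XML surrogate (one `<element>` per region with `<vertex>`
children, one `<point>` per field centre, coordinates printed at 0.01 µm)
plus flat CSVs. Export→parse is the identity to the printed precision.
ROI polygons are exported at full traced resolution; no vertex decimation
is applied.

## High-content phenotype scoring

Two phenotypes are scored per field: rosettes per nucleus, and gelatin area
degraded per cell (in situ zymography, where degradation reads out as dark
holes in a fluorescent matrix).

- **Illumination correction** divides by an illumination estimate and
  rescales to preserve the image mean. The estimate is a heavy Gaussian
  smooth (default σ = 50 px, which damps objects) followed by an
  interior-weighted second-order polynomial surface fit. The polynomial
  step exists because plain smoothing flattens a gradient near the border
  and leaves a ~5% residual there; the fitted surface extends the gradient
  cleanly to the edges (residual < 2% on a 20% linear gradient).
- **Top-hat enhancement** (white top-hat, disk radius 10 px) keeps features
  narrower than the disk and suppresses broad plateaus.
- **Object detection**: automated threshold (Otsu default for this stage),
  hole filling, connected components, then refinement by area (10–200 µm²),
  major *and* minor axis length (2–20 µm) and solidity (≥ 0.8). The
  numeric cut-offs are package defaults — the workflow they mirror leaves
  them unrecorded — chosen so that 5–7 µm compact blobs pass and
  20 × 1 µm fibers fail both the axis and solidity cuts. There is no
  declumping: touching objects count as one, by design.
- **Nuclei** are counted by primary-object detection with only a minimum
  area (20 µm²); merged nuclei count as one.
- **Degraded area** is the calibrated area below an automated threshold on
  the (optionally corrected) gelatin channel, divided by the nucleus count.
  An unthresholdable (uniform) gelatin image means zero degradation.

**Group statistics**: one-way ANOVA across conditions, then each condition
against the control by two-sample t-test with Bonferroni correction
(p_adj = min(1, m·p_raw), m = number of comparisons), significance at
p < 0.05. Degenerate inputs (zero variance in every group) return p = 1
when all means agree and p = 0 otherwise, with a warning.

## SILAC specificity filtering and enrichment

Cells are metabolically labeled with ¹³C6-lysine and ¹³C6-arginine
(+6.02013 Da per labeled residue). Classification of each identified
peptide:

- **labeled** — every K/R in the sequence carries the ¹³C6 modification;
- **contaminant** — at least one K/R is unmodified (partial labels count
  as contaminant: metabolic incorporation is verified complete, so a
  half-labeled identification is an artifact);
- **indeterminate** — no K/R in the sequence; excluded from the
  contamination fraction, which is contaminants / (labeled + contaminants).

A modification placed on a residue outside the labeling scheme, or
disagreeing with the sequence, is a data-integrity error, not a
classification outcome.

**Protein inference** uses labeled peptides only: specific peptides
(assigned to exactly one protein group, as flagged in the input table; no
razor-peptide logic) are grouped by accession, proteins with at least 2
specific peptides are retained (configurable), and protein abundance is the
sum of specific-peptide MS1 areas. Abundances are normalized by each
sample's total (fractions summing to 1), which makes enrichment ratios
invariant to global rescaling of either sample. A protein is **enriched**
when normalized rosette/total ≥ 1.5, inclusive (log2(1.5) ≈ 0.585, the 0.6
seen on log-ratio axes). Proteins detected in only one sample are reported
as `rosette_only`/`total_only` with an undefined ratio and are never
flagged enriched — no infinite ratios.

**Sample quantity** is estimated from a standard curve: ordinary
least-squares (free intercept) of summed ¹³C-peptide MS1 area against
injected quantity; the estimate is (area − intercept)/slope, with a warning
when it extrapolates beyond twice the largest fitted point. The nearest
reference injection is chosen on the **log scale** (dilution series are
logarithmic; 72 ng is closer to 100 ng than to 50 ng in that metric), with
ties resolved to the larger point.

**Replicate overlap** reports both the overlap coefficient
(|A∩B|/min(|A|,|B|), the default) and Jaccard (|A∩B|/|A∪B|), because which
denominator the original comparison used is not recorded. Annotation
tabulation is a plain join against a user-supplied protein→class table;
no live database queries.

## Synthetic data: what it emulates and what it does not

All tests and the acceptance script run on seeded synthetic data with known
ground truth; identical parameters and seed give bit-identical outputs
(one `numpy` Generator per call).

**Rosette fields** (default 384×384 px at 0.25 µm/px): rosettes are annuli —
bright ring of thickness 1 µm between r_in and r_out, dimmer core at 35% of
ring amplitude — with diameters uniform in 5–7 µm, centres separated by at
least one diameter plus 2 µm and kept clear of the border. Distractors are
20 × 1 µm bright bars at random orientation (aspect ratio 20, far below the
circularity floor), placed at least 3 µm from any rosette edge: a 2-px
median plus 1-px closing can bridge gaps under ~4 px, so nearer fibers
would merge with rings and the field would no longer represent
well-separated objects. Objects are rendered with 4×4 subpixel coverage
(anti-aliasing — the correct rasterization of the continuous shapes;
hard-thresholded rendering aliases the 2-px ring wall badly enough that
the median filter can break small rings). A multiplicative linear
illumination gradient (default 15% peak-to-peak) and additive Gaussian
noise are applied last; ring amplitude is 100 intensity units over a
background of 10, so `noise_sd = 20` is a ring SNR of 5.

The default sampling of 0.25 µm/px is chosen so the 1-µm-wide structures —
the ring wall and the fibers — are 4 px wide and pass through the
radius-2 median filter intact at any orientation. At 0.5 µm/px those
structures are 2 px wide, and a radius-2 median all but erases a 2-px
*diagonal* band (most of its disk neighborhood is background), leaving
near-threshold residue that noise then shreds into short stubs; such stubs
can genuinely pass an area ≥ 10 µm² + circularity ≥ 0.35 filter, which
would misrepresent the well-resolved imaging the filters were designed
for. At 0.25 µm/px a fiber fragment of ≥ 10 µm² is necessarily ≥ 10× as
long as it is wide (circularity ≤ 0.26), so distractors fail the filter by
construction. Not simulated:
point-spread function, cell bodies, intensity heterogeneity within a ring,
or overlapping structures — passing tests show the operator chain is
correct and robust to noise and distractors, not that it handles crowded
or out-of-focus real fields.

**Zymography pairs**: the gelatin channel is uniform (200) except dark
holes (20) rendered as the exact pixel set closest to each hole centre with
`round(area/pixel²)` pixels, so the ground-truth degraded area is exact by
construction; nuclei are disks of ~8 µm. Default noise σ = 3.

**Peptide tables**: tryptic-like sequences (7–20 residues, C-terminal K/R),
one ¹³C6 modification per K/R on labeled rows, none on contaminant rows;
MS1 areas are log-normal with multiplicative noise (log-normal,
mean-preserving) at a configurable CV. A chosen fraction of proteins is
spiked by the enrichment factor in the rosette channel, and the remaining
proteins are proportionally depleted so both channels have equal totals.
The depletion is what makes the spike exactly recoverable: total-intensity
normalization rescales every ratio by Σa/Σ(aE), so without balancing, no
construction could return the spiked factor exactly. It is also the
physically consistent picture — a compartment enriched for some proteins
necessarily holds a smaller share of the rest. Because abundances are
heavy-tailed, the enriched subset is re-drawn (seeded) if a single huge
protein would make the balance infeasible.

## Problem sizes and defaults

| Parameter | Default | Why |
| --- | --- | --- |
| median radius | 2 px | as published |
| rolling-ball radius | 20 px | as published |
| min area | 10 µm² | as published |
| circularity | [0.35, 1] inclusive | as published |
| enrichment ratio threshold | ≥ 1.5 inclusive | as published |
| min specific peptides | 2 | as published |
| threshold method | IsoData (midrange-initialized) | closest to the original macro environment; Otsu selectable |
| closing element | disk, 1 px | unrecorded in the original; smallest that bridges 1-px ring breaks |
| connectivity | 8 | matches particle-analysis behavior; 4 selectable |
| pixel size (synthetic) | 0.25 µm/px | resolves the 1 µm ring wall and fiber width (see below) |
| HCA area / axes / solidity | 10–200 µm² / 2–20 µm / ≥ 0.8 | unrecorded in the original; separate 5–7 µm blobs from 20×1 µm bars |

The acceptance script uses 50 synthetic fields for count recovery and 50
peptide tables for ratio-error statistics — large enough for stable
percentages, small enough to run in under a minute on one CPU.

## Known limitations

- The exact auto-threshold variant and closing element of the original
  macro are unrecorded; both are configuration here, and the IsoData
  initialization documented above is this package's choice.
- Whether the original circularity used a smoothed perimeter is unknown;
  the estimator above is documented and tested instead.
- No declumping anywhere: merged rosettes, nuclei or objects count as one.
- The element-file schema is an open surrogate, not the instrument's
  proprietary format; a converter is required to drive a real instrument.
- Protein-level input is CSV/TSV; spectra, search-engine scoring, FDR and
  retention-time alignment are out of scope.
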