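# Methods

## Problem and scope

`adipoquant` quantifies adipogenic differentiation of mesenchymal stromal
cells (MSCs) from multichannel 2-D microscopy.  The biological readout is
the fraction of cells that have accumulated lipid droplets, measured in two
workflows:

1. **Nile Red workflow.**  Cells are segmented from the red Nile Red
   emission channel (total lipids, which stains the whole cytoplasm),
   droplets from the green emission channel (non-polar lipids), and a cell
   is counted as differentiated when its region intersects the droplet
   mask.  The headline statistic is `100 · n_droplet_pos / n_total` per
   well, compared across conditions with a Kruskal–Wallis test.
2. **Rescue workflow.**  Cells are segmented by nuclei-seeded watershed
   from the DAPI channel; per cell, the maximum of the auto-contrast-
   normalized GFP channel (transgene expression) and the maximum of the
   per-pixel Oil Red O ratio R/(G+B) are recorded; cells are gated into
   GFP × ORO quadrants (GFP > 127 on the 0–255 scale, ratio > 1, both
   strict), and the double-positive count is the readout.

The package assumes pre-aligned channels; registration between live and
fixed imaging stages, neural-network training, and all wet-lab protocol
steps are out of scope.

## Synthetic wells and what they do (not) emulate

Real micrographs for this assay are not publicly deposited, so validation
rests on a synthetic-well generator with exact per-cell ground truth.

**Geometry.**  Cells are randomly perturbed ellipses around a circular
nucleus (radius 4 px), placed by sequential random placement with a hard
minimum centre spacing (30 px default).  Semi-axes (cell radius
~N(11, 1.5) px, axis perturbation U(0.85, 1.25)) are capped at
`min_spacing/2 − 1`, so no cell crosses the midline to a neighbour; every
pixel of a cell is strictly closer to its own nucleus than to any other.
This makes the proximity partition around detected nuclei exact up to
discretization, which is deliberate: it lets gating errors be attributed
to detection and thresholding rather than to an unknowable cell-shape
model.  Real confluent monolayers have irregular, interdigitating
boundaries; passing tests on these wells therefore validates the
*pipeline logic* (thresholds, selection, gating, counting), not boundary-
accurate segmentation of hard-to-separate cells.

**Composition.**  `adipocyte_fraction` and `gfp_fraction` are realised as
exact rounded counts drawn uniformly among cells, so a well's true
fraction equals the requested one up to rounding (the default fraction,
0.085, sits in the middle of the 0.6–24.6% range the assay is used for;
the default GFP fraction for rescue fixtures is 0.10, matching a typical
lentiviral transduction efficiency for this cell type).  With
`gfp_suppresses_droplets`, adipocytes are drawn only from GFP-negative
cells, emulating a functional rescue construct.  Droplet regimes: *small*
= 3–8 disks of radius 2–4 px per adipocyte; *large* = one disk of radius
0.5 × the cell's minor semi-axis; these sizes are free parameters chosen
to reproduce the qualitative small/large contrast, not measurements.
Droplet pixels are clipped to their cell; each adipocyte is guaranteed at
least one droplet pixel.

**Intensities.**  Channels are flat foreground/background levels plus
additive Gaussian noise, clipped to the bit-depth range (16-bit defaults:
background 500, nucleus 20 000, cytoplasm 10 000, droplet green 15 000,
GFP 18 000, noise SD 300).  The Oil Red O image is 8-bit RGB with droplet
pixels at (200, 45, 45) — ratio ≈ 2.2 — cell pixels at (180, 160, 160)
and background (220, 220, 220), noise SD 3; at these levels ≥ 99% of
droplet pixels remain ratio-positive after noise.  No optics are
simulated (no PSF, no vignetting, no uneven illumination, no z-structure),
so threshold-based steps are easier here than on real data; the manual-
threshold interface exists precisely because real experiments need a
hand-picked, experiment-wide constant.

**Determinism.**  `generate_well` is a pure function of its config
(including the seed); all randomness flows through one
`numpy.random.Generator`.

## Segmentation

**Nuclei ("bright spots").**  Gaussian smoothing (σ = 2 px) → Otsu (or
explicit) threshold → removal of components < 10 px → one seed per
component at its intensity-weighted centroid → greedy minimum-distance
filtering (default 8 px), keeping the brighter seed of any close pair.
Constant images yield an empty seed set rather than an error.

**Seeded watershed.**  `segment_cells_watershed(seeds, support, mask)`
floods `support` from the seed markers restricted to the foreground; with
`support=None` it uses the negated distance transform of the foreground
(the default; flooding an intensity landscape is supported by passing it
explicitly).  Seeds outside the foreground are dropped with a warning.
The rescue pipeline builds its foreground as all pixels within
`cell_reach` (default 18 px) of a detected nucleus and floods the
distance-to-nearest-nucleus map, i.e. a reach-limited proximity
partition.  Watershed tie-breaking follows the deterministic FIFO
flooding of scikit-image; identical inputs give identical label masks.

**Lipid-red segmenter.**  Otsu (or explicit) threshold → hole filling →
removal of objects < 30 px (debris) → markers at local maxima of the
σ = 2-smoothed distance transform with 16 px minimum separation (every
foreground component is guaranteed at least one marker: its distance-
transform argmax) → watershed on the negated smoothed distance transform.
This is a classical stand-in with the same contract as a trained
instance-segmentation network, which can replace it behind the same
interface.  Regions use 4-connectivity; edge-touching cells are kept.

## Scoring and gating conventions

- Droplet segmentation uses `green >= threshold` (inclusive) and removes
  components below `min_droplet_area` (default 4 px, suppressing
  single-pixel noise; 0 disables).  The threshold is explicit input and
  recorded output, never hidden state, so one manually chosen value can
  be applied across all wells of an experiment.
- Oil Red O ratio: `R/(G+B)` per pixel, positive when **strictly** > 1.
  Zero denominator: R > 0 → `inf` (pure red is maximally positive);
  R = 0 → ratio 0, negative.  Positivity is invariant under uniform
  rescaling of all three planes.
- Auto-contrast: `channel · 255 / max(channel)`, kept in floating point;
  the GFP gate (strictly > 127) is applied on this continuous scale.  An
  all-zero channel is returned unchanged with a warning — rescaling pure
  background would manufacture a spurious 255.  Consequently the gate is
  only meaningful within one image, not across images with different
  transduction constructs.
- "Having" selection counts a cell when ≥ `droplet_overlap_min`
  (default 1) of its pixels are droplet pixels.
- Field-sampling estimator: rectangular fields are placed uniformly with
  periodic (wrap-around) boundaries, so every cell has equal inclusion
  probability and the estimator has no border bias; cells are assigned by
  centroid and deduplicated across overlapping fields.  A field the size
  of the image reproduces the whole-well percentage exactly.
- Fold changes are ratios of the one-decimal percentages as reported,
  rounded half away from zero to one decimal.

## Statistics

- Kruskal–Wallis (tie-corrected, via scipy) with Dunn pairwise z tests
  (tie term `Σ(t³−t)` in the variance) and Holm adjustment.  Dunn + Holm
  and Tukey HSD after ANOVA are conventional choices where only
  "multiple comparisons" / "post hoc" is specified; both are stated in
  the reports.  An all-identical-values input returns H = 0, p = 1.
- Two-way ANOVA uses type-II sums of squares (equal to classical ANOVA on
  balanced designs) via statsmodels, requiring ≥ 2 replicates per design
  cell; zero-sum-of-squares effects are reported as F = 0, p = 1.
- 2^−ΔΔCt: per sample, ΔCt = Ct_target − Ct_reference; relative
  expression is 2^−ΔCt divided by the **arithmetic mean** of the control
  group's 2^−ΔCt, so the control mean is exactly 1 for every gene.
  (Normalizing by the mean ΔCt instead would fix the control *geometric*
  mean at 1; the arithmetic convention matches "assuming as 1 the mean
  level of each transcript in the control group".)  Both coincide when
  control ΔCt values are equal.
- Eluted-dye quantification: absorbance at 500 nm divided by protein
  content; protein from an OLS line through BSA standards (duplicates at
  equal concentration averaged first), inverted for prediction; a
  zero-slope curve raises.

## Problem sizes used in validation

Fraction-recovery runs use 1000 cells per 1600 × 1600 px well at
generator fractions 1, 5, 10 and 25%, five seeds per setting, with the
manual droplet threshold 7750 (midway between the background and droplet
foreground of the default 16-bit intensity model).  Rescue-gating checks
use 500 cells per 1024 × 1024 px well at 10% GFP.  Oracle-equivalence
checks use 100 random 64 × 64 instances; Kruskal–Wallis calibration uses
2000 null replicates of 4 × 10 standard normals.

## Known limitations

- The generator's cells never overlap or cross the inter-nucleus midline;
  performance on truly confluent, irregular monolayers is untested here
  and in practice depends on the segmenter (the module contract admits a
  trained network).
- Otsu thresholding of the droplet channel is unreliable when droplets
  occupy a very small pixel fraction (rare-adipocyte wells); use an
  explicit experiment-wide threshold there, as the manual procedure does.
- Whole-image percentages are pooled counts per well; no within-well
  spatial statistics beyond the field-sampling estimator.
- Repeated-measures ANOVA (time-course secretion data) is not
  implemented.
- The fold-change helper reproduces printed-percentage arithmetic; when a
  reported fold value disagrees with the ratio of its own printed
  percentages, the computed ratio is returned (no attempt is made to
  reverse-engineer inconsistent roundings).
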