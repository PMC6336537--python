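# Methods

`toposcreen` reconstructs, as runnable and tested code, the analysis behind a
micro-topography ("TopoChip") screen of keratinocyte terminal
differentiation: a library of randomized surface topographies, the
descriptors that summarize each topography, a simulated high-content screen
with a planted topography → phenotype structure, the image-analysis
quantification of differentiation and cell shape, robust hit calling, and
classification-tree modelling of which surface properties drive the
phenotype.  Because the underlying screen data exist only as published
summaries, the package's empirical claims are properties: exact geometry and
statistics oracles, and recovery of the structure its own generator plants.

## Virtual topography library

A TopoUnit is a 300 × 300 µm well carrying one topography built from
primitives (circles, equilateral triangles, rectangles).  The default
generator draws, per design, a primitive count uniform on 1–30, a kind
uniform over the three shapes, sizes uniform on 3–80 µm (circle diameter,
triangle side, rectangle length; rectangle width is a uniform 0.05–1.0
fraction of length), positions continuous in the unit, and rotations uniform
on [0, 360).  The 3–80 µm size default was chosen so that the library's
coverage distribution spans the decision thresholds the screen operates at
(coverage ≈ 0.26–0.40; see "Planted model"): a library whose coverage never
reaches those values could not exercise the analysis.  One flat control
(empty design) is always appended.  The default chip is a 66 × 66 grid with
every design placed twice, the duplicate displaced by (+33, +33) modulo the
grid so duplicates never share a row or column (guarding against position
bias); with 2175 designs plus the control this occupies 4352 of 4356
positions.

Rasterization uses a pixel-center inclusion test at 0.5 µm/px by default
(600 × 600 px per unit), keeping masks strictly binary as the coverage
descriptor requires; the smallest screen-relevant scale (≈ 8 µm circles) is
resolved with > 16 px across.  Coverage of rasterized single primitives
agrees with exact (shapely) geometry to well under 1%.

## Topography descriptors

- **FCP** — covered pixel fraction of the mask.
- **FCPN01** — FCP under added variation: every pixel flips with
  probability 0.01 and the covered fraction is averaged over 25 replicates
  (expectation `fcp·0.99 + 0.01`).  The replicate statistic depends on the
  flips only through two binomial counts, which are drawn directly.
- **WnX** — share of the mask's non-DC spectral power in radial
  spatial-frequency bands.  The band scale is cycles per 10 µm with centers
  {0.1, 0.2, 0.3, 0.5, 1, 2, 4}; edges are geometric midpoints, the lowest
  edge sits just above DC and the highest band is open-ended so the bands
  tile the whole non-DC spectrum and sum to 1.  This choice spans spatial
  periods from ≈ 2.5 µm to the unit scale, bracketing the 3–80 µm primitive
  sizes.  The annular sum is exactly invariant to cyclic translation and 90°
  rotation.
- **LineLen / CircDiam** — mean rectangle length over "line" elements
  (aspect ratio ≥ 3) and mean circle diameter, taken from the in-silico
  design metadata (the designs, not the images, define these sizes).  Absent
  when a design has no qualifying primitives.
- **RotSD** — sample standard deviation of primitive placement angles, an
  irregularity measure.  Circles are excluded (no orientation).  By default
  each angle is folded into its primitive's rotational symmetry period
  (triangle 120°, rectangle 180°) and rescaled to a common [0, 180) range; a
  `fold_by_symmetry=False` flag keeps raw [0, 360) angles, which matches
  published RotSD values above 90°.  Linear (not circular) SD is used to
  match the scale on which such values are reported.

## Synthetic screen and planted model

The generator emulates the screen's observed regime: 5–25 cells per unit
(uniform), one static 24 h snapshot (no proliferation or detachment), cells
independent of one another (differentiation in the screen did not track cell
number).  A unit's planted differentiation probability and morphology follow
an ordered rule list over its descriptors; the default rules use the
screen's published split values as thresholds:

| rule | predicate | p(differentiate) | morphology |
|---|---|---|---|
| 1 | FCP ≥ 0.256 and CircDiam ≥ 8.293 µm | 0.50 | round |
| 2 | FCP < 0.256 and LineLen < 15.849 µm and (FCPN01 < 0.397 or RotSD ≥ 40.876°) | 0.45 | spread |
| 3 | FCP < 0.256 and LineLen < 15.849 µm | 0.45 | round |
| — | baseline (no rule matches, including the flat control) | 0.12 | round |

The rule probabilities mirror the reported extremes (units with 50–60%
differentiated cells) and the baseline the typical 5–30% range; they are
generator parameters, not estimates.  Predicates on absent descriptors are
false, so e.g. the flat control always falls to baseline.

Per cell: TGM1 median fluorescence intensity is Normal(600, 120) for
differentiated and Normal(80, 40) truncated at 0 for undifferentiated cells,
so the standard MFI > 270 positivity cutoff sits between the modes with
< 0.5% misclassification on either side.  Morphology draws area from a
log-normal (median 500 µm² round, 1800 µm² spread, 700 µm² undifferentiated;
σ_log 0.3) and roundness from a Beta with mean 0.70 / 0.30 / 0.55
(concentration 20), so the screen's working cutoffs (spread area 1272 and
670 µm²; roundness 0.62 and 0.38) fall between class modes.  The perimeter
is defined by the circularity identity `P = sqrt(4π·A / roundness)`, making
the per-cell isoperimetric relation exact by construction.  Nucleus centers
are placed with a 20 µm minimum spacing.

**Rendering.** Units can be rendered as 3-channel stacks: DAPI (10 µm
nucleus disks), F-actin (cell body at intensity 200), TGM1 (cell body at the
cell's MFI), plus a ground-truth label raster, with optional Gaussian noise.
Each cell is a rotated ellipse whose axes are solved (Ramanujan perimeter)
to reproduce its (area, roundness).  Where ellipses overlap, pixel ownership
is resolved by nearest-nucleus flooding within the union foreground — the
same assignment rule the segmentation stage uses, and the renderer floods
from scan-order-relabeled markers, so a noise-free rendering round-trips
through segmentation exactly (same counts, same per-cell MFI medians).

**What the generator does not emulate:** cell–cell adhesion and colony
effects, intra-cell intensity texture, uneven illumination, imaging
artifacts (bubbles, debris), proliferation, and any pharmacological
perturbation.  Passing tests therefore demonstrate that the analysis
recovers structure of this idealized data-generating process, not that it
would perform identically on microscope data.

## Morphometry

Nuclei: global Otsu threshold (overridable), 8-connected components,
components below 40 µm² removed.  Cells: thresholded F-actin foreground
partitioned among nuclei by nearest-seed flooding (watershed of a constant
image restricted to the foreground); a nucleus stranded outside the
foreground keeps a nucleus-sized cell and is flagged.  Per cell: area is
pixel count × resolution², TGM1 MFI is the median intensity over the cell's
pixels, and roundness is always recomputed as `4π·area/perimeter²`.

The perimeter estimator is a smoothed marching-squares contour: contours at
level 0.5, a circular moving average (window 5 vertices), then polygon
length.  Raw marching-squares staircases inflate a disk's perimeter by ≈ 5%
(circularity ≈ 0.90) and Crofton 4-direction estimates inflate a square's
circularity to ≈ 0.88; the smoothed contour scores disks at 0.993–0.998
across radii 5–50 µm (0.25 µm/px) and squares at 0.789 (axis-aligned) and
0.782 (rotated 30°) against π/4 ≈ 0.785.  Cells touching the unit border
are retained.

Positivity is strict (`MFI > cutoff`, default 270; the cutoff is a config
key).  Unit summaries report % positive, average spread area (total
positive-cell area over the positive count) and mean roundness of positive
cells; shape statistics are undefined (and excluded downstream) when a unit
has no positive cell.

## Hit selection

For a chosen metric, cutoffs are recomputed per dataset: high if value >
median + k_top·SD, low if value < median + k_bottom·SD (sample SD over
units with a defined metric; strict inequalities).  Defaults follow the
screen's conventions: k = (+2, −2) for % positive, (+2, −0.5) for spread
area, (+2, −1) for roundness.  Because the % positive distribution is
bounded below and right-skewed, its SD-based bottom cutoff can fall below
zero and call nothing; the pipeline therefore labels the "low" class by a
bottom quantile (default 0.25) for the modelled metric, with the SD rule
available by configuration.  Design-level labels join duplicate units by
"either duplicate qualifies"; a design qualifying as both high and low is
excluded with a warning.

## Tree modelling

Features with pairwise Pearson r² > 0.75 are eliminated (later column in
canonical order drops; zero-variance columns drop first) — by construction
this removes FCPN01 in favour of FCP.  Descriptors undefined for a design
are imputed with sentinels placed on the side of the range where the
stimulating property is absent: no line elements → 999 µm, no circles →
0 µm, no orientable primitives → 0°.  Designs split 75/25 stratified by
class.  The tree is CART: exhaustive Gini search over midpoint thresholds,
`min_leaf` 8, `max_depth` 5, ties broken by canonical feature order then the
smaller threshold; cost-complexity pruning with the penalty chosen by
10-fold cross-validated misclassification under the one-standard-error rule
(the largest penalty within one binomial SE of the CV minimum).  Held-out
performance is the ROC/AUC of the leaf scores, computed as the mid-rank
Mann–Whitney statistic (identical to the trapezoidal ROC area).

A null note: with labels at the screen's hit-class imbalance (≈ 30% high),
cross-validated one-SE pruning collapses pure-noise trees to a single leaf
essentially always; with perfectly balanced 50/50 noise the one-SE rule (in
this implementation and in reference CART implementations alike) keeps
spurious splits roughly half the time.  The null guarantees stated in the
tests are therefore at the imbalanced composition the screen actually
produces.

**Recovery criterion.** A fitted tree "recovers" the planted structure when
the features of its top two split levels intersect the planted rule features
{FCP, FCPN01, LineLen, CircDiam, RotSD}.  Over 20 re-seeded default screens,
recovery with held-out AUC ≥ 0.7 holds in ≥ 18 seeds (in practice 20/20,
with AUC ≈ 0.99: the planted rules are deterministic functions of the
descriptors, so labels are far more separable than wet-lab hits — the
published AUCs of ≈ 0.7 reflect biological and measurement noise the
generator does not model).

## Pipeline, determinism and problem sizes

`run_pipeline` executes design → rasterize → descriptors → simulate →
quantify → hits → labels → tree → report, writing every table plus a
manifest with all seeds and SHA-256 hashes of every artifact; identical
configurations produce bit-identical artifacts.  Table mode (cell tables
straight from the simulator) is the default; image mode renders a
configurable subsample (default 200 units) and is tested to agree exactly
with table mode at zero noise.

Default problem sizes keep a full run desk-scale: descriptor extraction for
2176 designs ≈ 30 s, one simulated chip (4352 units, ≈ 65k cells) a few
seconds, the 20-seed recovery experiment ≈ 4 minutes in total on one CPU.

## Known limitations

- LineLen/CircDiam come from design metadata; a fully image-side pipeline
  would estimate them from masks.
- The WnX band convention (cycles per 10 µm, geometric edges) is this
  package's definition; published values use an unspecified convention and
  are not directly comparable.
- The hit/label construction models one chip; multi-experiment pooling is
  limited to a simple union of per-run labels.
- Rendered images are idealized (constant-intensity ellipses); segmentation
  robustness is only demonstrated against additive Gaussian noise.
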