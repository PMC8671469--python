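# Methods

This note documents the models behind `neurowell`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
validation does and does not establish about real microscope data.

## Synthetic well model

The simulator renders per-channel 16-bit rasters of a circular well of
diameter 6,400 µm (standard 96-well) at a configurable pixel pitch and
returns, alongside the images, the generating truth: cell centres,
alive flags, per-region counts, the analytic total neurite length, and
the rasterized soma/neurite/background compartment masks.

**Cell placement.** Radial positions are drawn by inverse transform
from the density

$$f(r) \propto r\left(1 + b\,(r/R)^4\right), \qquad 0 \le r \le R,$$

with angle uniform. At edge bias $b = 0$ this is exactly
uniform-over-area sampling ($r = R\sqrt{U}$); growing $b$ moves
probability mass to the rim, reproducing the aggregation of cells near
the well edge seen when plates are moved to the incubator before cells
settle. The normalising integral is available in closed form, and the
CDF is inverted on a 4,097-point grid. The exponent 4 makes the bias
term negligible in the well centre while steep at the rim; the
magnitude of $b$ is calibrated only qualitatively, since no
quantitative spatial statistic of a badly plated well beyond regional
occupancy SDs was available ($b = 5$ is used as the "no settling"
condition throughout).

**Nuclei and somata.** Per-cell disc radii are Gaussian (nucleus
5 ± 0.8 µm, soma 8 ± 1.5 µm). Discs may overlap at high density — no
collision rejection — which deliberately reproduces the nuclear
clustering that makes counting hard at 15,000 cells/well.

**Neurites.** Each live cell grows 1–4 processes as piecewise-linear
random walks: 5 µm steps, Gaussian turning angle (SD 20°), per-neurite
target length 60 ± 20 µm by default, starting on the soma rim heading
along the outward normal ± 60°. The outward heading matters: processes
extend away from the cell body, and a simulator that points them
uniformly sends half of each first segment back across the soma where
no soma-excluding length measure could ever see it. Walks that would
leave the raster are truncated, and the recorded ground-truth length is
the summed length of the steps actually drawn, so truth equals the
rasterized polyline length exactly. Polylines are dilated to a 2 µm
width; widened pixels inherit the value of the nearest centre-line
pixel.

**Intensity model.** The βIII-tubulin channel uses a three-compartment
contrast with defaults soma 2542 ± 743, neurite 769 ± 327 and
background 264 ± 35 counts — the measured structure of a differentiated
SH-SY5Y network, in which the soma is about three times brighter than
the neurites and faint distal neurites sit just above background.
Those SDs describe point-to-point spread within a compartment, so the
generator realises them accordingly: neurite intensity is drawn per
5 µm step (floored at background + 2 noise SDs, keeping faint
stretches visible in principle), and the soma SD is split evenly in
variance between a cell-level and a pixel-level component. Every
channel sits on a flat background mean with additive Gaussian read
noise (SD 35), clipped to [0, 65535] and quantised to uint16. Calcein
marks live-cell bodies only, EthD-1 dead nuclei only.

**Determinism.** All draws come from one `numpy` generator seeded by
the config; identical configs give bit-identical images and truth.

What the simulator does **not** emulate: point-spread-function optics,
stitching artefacts, uneven illumination, autofluorescence gradients,
neurite branching, debris, or out-of-focus fields. Passing
ground-truth-recovery tests therefore shows the estimators are correct
for clean, flat-field images with known geometry — not that they are
robust to every artefact of real acquisitions, where the documented
config knobs (smoothing, thresholds, pruning) may need retuning.

## Homogeneity scoring

The well disc is partitioned into a central disc holding one fifth of
the area (radius $R/\sqrt 5$) plus the outer annulus cut into four
equal quadrant sectors; ring/sector counts and the sector offset are
configurable. Foreground is Otsu on the σ = 2 px Gaussian-smoothed
nuclear channel, with the threshold computed over well-interior pixels
only — rim glare and the dark exterior otherwise bias the histogram.
Occupancy is a binary area fraction (no intensity weighting), and the
score is the sample SD (n − 1 denominator, the spreadsheet/Prism
convention; population SD selectable). A fully saturated interior
(every pixel at 65535) yields a warned profile of 100s; a constant
interior yields a warned profile of zeros.

Well geometry can be supplied or detected: detection takes the minimum
enclosing circle of the convex hull of the Otsu foreground, which on
simulated wells recovers the centre within 5 px and the radius within
2%; callers with stage metadata should override it.

## Nuclei counting and viability

Counting: Gaussian smooth (σ = 2 px) → Otsu → fill holes →
distance-transform watershed seeded at distance maxima at least 4 µm
apart → drop fragments below 25% of the median object area. The 4 µm
separation (roughly one nucleus radius) was validated against
simulator truth: counts recover within ~5% at 2,500 cells/well density
and within ~15% at 15,000, where clustering genuinely merges nuclei.
A guard rejects noise-only images: if the Otsu classes are separated by
fewer than 4 background SDs the image is treated as empty — otherwise
pure read noise on, say, an EthD-1 channel with no dead cells would be
segmented into thousands of false objects. The original assay counted
nuclei manually; this automated counter replaces that step and its
accuracy claim rests on the simulation results above.

Reader-based viability subtracts the mean blank (medium + matrix)
emission per filter, floors negatives at zero (physically meaningless),
and reports EthD-1/calcein rounded to 3 decimals in summary tables,
matching the precision such ratios are conventionally reported at.
Zero live signal flags the well rather than erroring. Image-based
viability counts per-channel objects with the same segmentation and
reports dead/live counts.

## Neurite segmentation and length

Background statistics (mean, SD) come from the below-Otsu pixel
population of the smoothed βIII channel. The chain is:

- **Soma mask** — pixels above background mean + 8 SD, opened with a
  2.5 µm-radius disc (wider than a neurite, smaller than a soma, so
  attached processes are not swallowed), kept if ≥ 50 µm² and
  overlapping nuclear foreground. With no nuclear signal nothing is
  accepted as soma.
- **Neurite foreground** — union of (a) a global Otsu on the
  background-subtracted channel and (b) a multi-scale Sato tubeness
  response (σ ∈ {1, 2, 4} px) thresholded with Li's minimum
  cross-entropy method. Li rather than Otsu on the ridge response is a
  deliberate choice: the ridge histogram is dominated by its
  bright-soma mode, and Otsu's threshold then misses roughly half of
  the faint distal neurite pixels that the dual design exists to
  recover; Li detects ~93% of ground-truth neurite pixels at ~1–3%
  background false positives on simulated fields.
- **Skeleton** — topology-preserving thinning of the union, soma
  pixels removed, terminal spurs shorter than 3 µm pruned (suppresses
  thinning artefacts without deleting genuine short branches;
  configurable), then re-thinned so the output is a fixed point of
  skeletonization.
- **Length** — chamfer path-step summation over the 8-connected
  skeleton: 1 pixel pitch per orthogonal adjacency, √2 per diagonal.
  This is the standard cheap estimator, within ~2% for smooth curves.

Spur pruning walks inward from each endpoint to the nearest junction
and deletes sub-threshold branches, including the attachment pixel when
its remaining neighbours stay mutually connected (removing it cannot
split the skeleton).

This segmentation is a self-contained re-implementation of the
neurite-network analysis stage; it makes no claim of pixel
compatibility with any particular FIJI macro. On simulated fields at
2,500 cells/well density the recovered total length lands within
10–15% of the analytic truth across total-length scales of roughly
500–10,000 µm, with a systematic few-percent underestimate from
skeleton corner-cutting, soma-junction exclusion and tip pruning.

The outgrowth statistic is total skeletal length divided by the nuclei
count, in µm per nucleus by default (a pixel-based unit is selectable;
between-condition comparisons are ratios and hence unit-free). Images
with zero nuclei are flagged, not averaged.

## Statistics

One-way fixed-effects ANOVA is computed from the classical sum-of-
squares decomposition with a Shapiro–Wilk test on pooled residuals.
Conventions for degenerate inputs: all groups identical → F = 0,
p = 1; zero within-group variance with unequal means → F = ∞, p = 0
(the vanishing-error limit); constant residuals → normality statistics
are NaN. Tukey HSD uses the studentized range via statsmodels and
handles unbalanced groups as Tukey–Kramer. Stars follow
* p < 0.05, ** p < 0.01, *** p < 0.001, **** p < 0.0001.

Dose–response summaries treat each image as the experimental unit by
default (three images × three wells gives n = 9 per condition);
aggregating to per-well means first (n = 3) is available by feeding
well means into the same summary. Blocks (timepoint × assay arm) are
analysed independently, with no correction across blocks, matching how
such panels are conventionally presented. Fold-change is the ratio of
condition mean to control mean.

The type-I error of the ANOVA layer is checked by simulation: over
1,000 null datasets (three groups of three from one normal) the
rejection rate at α = 0.05 stays within [0.03, 0.07].

## Problem sizes used in tests

Full-well scans are rendered at 6.4 µm/px (≈1,000 px across the well;
12.8 µm/px for the bias-monotonicity sweep), which keeps 10,000-cell
wells fast while leaving nuclei 1–2 px — enough for area-occupancy
work. Counting and outgrowth fields use 0.65–1.3 µm/px on smaller
discs whose cell numbers are chosen to match the target areal density
(e.g. 156 cells on a 1,600 µm disc ≙ 2,500 cells/well); these sizes
were chosen as the smallest at which the estimators' behaviour is
representative, and recovery checks pool a few seeds per condition so
that single-field sampling noise does not dominate.

## Known limitations

- The edge-bias magnitude is qualitative; only the ordering of
  homogeneity scores between conditions is meaningful, not their
  absolute values.
- Neurites are branch-free; the length estimator handles crossings but
  its behaviour on heavily branched arbors is untested.
- Chamfer length is biased a few percent on digital curves; tolerances
  in the validation suite absorb this rather than correcting it.
- The well detector assumes cells reach near the rim; sparse or
  strongly centre-biased wells underestimate the radius, so supplying
  known geometry is preferred.
- 8-bit inputs are promoted by v · 257 with a warning; RGB and
  multi-page TIFFs are rejected rather than guessed at.
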