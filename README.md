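# neurowell

Quantification pipeline for high-content imaging of differentiated
SH-SY5Y cells in 96-well plates, with a synthetic well-image simulator
that provides ground truth for every stage.

Differentiated SH-SY5Y cultures are a standard neuron-like model for
plate-based screening, but turning their images into numbers requires a
chain of quantitative steps that are usually scattered across ad-hoc
scripts: checking that cells were plated evenly (edge effects ruin
downstream assays), counting nuclei to track proliferation across the
differentiation window, converting calcein-AM / ethidium homodimer-1
(EthD-1) fluorescence into a viability ratio, and measuring neurite
outgrowth from βIII-tubulin images. `neurowell` implements that chain
as a tested library plus a thin CLI, for assay developers and screeners
who need reproducible per-well readouts.

## The readouts

**Plating homogeneity.** A full-well nuclear-stain scan is partitioned
into five equal-area regions — a central disc of radius $R/\sqrt{5}$
plus four quadrant sectors of the surrounding annulus. With
$p_i$ the percent cell-occupied area of region $i$ (Otsu foreground on
the smoothed Hoechst channel), the homogeneity score is the sample
standard deviation $s = \sqrt{\tfrac{1}{4}\sum_i (p_i-\bar p)^2}$;
lower is more even.

**Proliferation.** Nuclei are counted by Gaussian smoothing, Otsu
thresholding, hole filling and a distance-transform watershed that
splits touching nuclei; the population change over differentiation is
$100\,(N_{\mathrm{end}}-N_{\mathrm{start}})/N_{\mathrm{start}}$ %.

**Viability.** From plate-reader tables, signals are blank-subtracted
per filter (floored at zero) and the dead:live index is
$\mathrm{EthD\text{-}1}/\mathrm{calcein}$; from image pairs, it is the
ratio of EthD-1-positive to calcein-positive object counts.

**Neurite outgrowth.** The βIII-tubulin channel is segmented by a
bright-blob soma mask plus the union of a global Otsu and a
multi-scale ridge (tubeness) detector for faint processes; the
foreground is thinned to a one-pixel skeleton, soma pixels removed,
short spurs pruned, and total length $L$ measured by chamfer path-step
summation. The outgrowth statistic is $L/N$ µm per nucleus, which
normalises for cell number between fields.

**Statistics.** Condition comparisons use one-way ANOVA with a
Shapiro–Wilk residual check and Tukey HSD (Tukey–Kramer when
unbalanced), plus dose–response summaries with fold-changes versus a
control group.

The simulator (`neurowell.simulate`) renders 16-bit wells with known
cell positions (uniform or rim-biased over the well disc), random-walk
neurites of known analytic length, a configurable
soma/neurite/background intensity contrast (defaults 2542/769/264
counts), and live/dead channel assignment — so every estimate above
can be validated against ground truth.

## Worked example

```python
import math
from neurowell import simulate, homogeneity, cells, neurites
from neurowell.config import SimulationConfig

# 1. simulate a uniformly plated well and score its homogeneity
cfg = SimulationConfig(pixel_size_um=6.4, n_cells=10_000, edge_bias=0.0,
                       neurites_per_cell=(0, 0), seed=7, channels=("hoechst",))
scan, truth = simulate.render_well(cfg)
partition = homogeneity.partition_well(scan)
profile = homogeneity.compute_occupancy(scan, partition)
print("occupied % per region:", [round(p, 1) for p in profile.occupied_pct])
print("homogeneity SD:", round(profile.homogeneity_sd, 3))

# 2. a differentiated field: count nuclei and measure outgrowth
field = SimulationConfig(well_diameter_um=660, pixel_size_um=0.65, n_cells=16,
                         seed=12, neurites_per_cell=(1, 4),
                         neurite_length_um=(60.0, 20.0))
scan, truth = simulate.render_well(field)
nuclei = cells.count_nuclei(scan.channel("hoechst"), field.pixel_size_um)
comp = neurites.make_composite(scan.channel("hoechst"), scan.channel("biii"),
                               field.pixel_size_um)
net = neurites.segment_neurites(comp, nuclei=nuclei)
print("nuclei:", nuclei.count, "(simulated:", truth.nuclei_count, ")")
print("total neurite length: %.0f um (simulated: %.0f um)"
      % (net.total_length_um, truth.total_neurite_length_um))
print("outgrowth ratio: %.1f um/nucleus" % (net.total_length_um / nuclei.count))
```

prints

```
occupied % per region: [22.6, 22.8, 22.5, 23.1, 23.4]
homogeneity SD: 0.377
nuclei: 16 (simulated: 16 )
total neurite length: 2319 um (simulated: 2475 um)
outgrowth ratio: 144.9 um/nucleus
```

The five regional occupancies of the uniform well agree to within a
percentage point, giving a low homogeneity SD (a rim-biased well under
`edge_bias=5` scores around 7–8). The outgrowth stage recovers the
simulated nuclei count exactly here and the analytic neurite length to
about 6%.

The same stages are available from the shell:

```sh
neurowell simulate --n-cells 10000 --pixel-size-um 6.4 --seed 7 --outdir out/
neurowell homogeneity out/plate1_A1_hoechst.tif --pixel-size-um 6.4 --outdir out/
neurowell stats --metrics-csv metrics.csv --outdir out/
```

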