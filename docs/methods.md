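# Methods

## Problem and approach

The package quantifies senescent cells from per-cell multi-channel image
stacks of the kind an imaging flow cytometer produces: one small bright-field
(BF) image plus fluorescence channels per cell. SA-β-gal activity is read as
BF darkening (X-gal precipitate); molecular markers (γH2AX foci, nuclear
HMGB1, Ki67, BrdU), cell-identity channels (CD45, pan-cytokeratin, GFP) and a
viability dye are read as fluorescence. Cells are classified by hierarchical
gating referenced to an unstained control sample, and populations are
summarized as percent positive and mean area ± SEM.

Commercial instrument software computes similar features with undisclosed
algorithms. Every operator here is therefore an open reconstruction from
standard primitives, chosen to preserve the measurement intent and validated
against ground truth from the package's own synthetic generator.

## Masks

Cell mask (BF) and nuclear mask (DAPI) share one recipe:

1. background = median of the 1-px image border;
2. deviation image |pixel − background| (cells may be darker or brighter
   than background);
3. Gaussian smoothing, σ = 2 px;
4. Otsu threshold, then **half-height refinement**: if half of the robust
   plateau height (0.5 × p90 of the above-threshold deviation) exceeds the
   Otsu value, re-threshold there. Background-dominated histograms push Otsu
   to ~0.4 of the object amplitude, which inflates an r = 8 px nucleus mask
   by ~11%; the refinement keeps mask areas of hard- and soft-edged disks
   within 5% of truth from r ≈ 8 px upward, without affecting large masks.
5. morphological closing (disk r = 2 px), hole filling, largest connected
   component (ties broken toward the image center).

A featureless image raises "no cell detected"; in the pipeline such cells
are logged, excluded, and counted against a run-level failure tolerance
(default 5%), mirroring debris frames in real acquisitions.

Per-channel background for feature values is the median of pixels outside
the cell mask dilated by 3 px (falling back to the image border if the
dilated mask covers the frame). Background is estimated per cell and per
channel, so slow illumination drift between frames cancels.

## Features

- `bf_mean_pixel`: mean background-subtracted BF pixel in the cell mask;
  negative for dark (SA-β-gal⁺) cells.
- `mean_pixel_<ch>`, `max_pixel_<ch>`, `intensity_<ch>`: mean, max and sum
  of background-subtracted pixels per fluorescence channel.
- `area_um2` = mask pixel count × pixel_size², with pixel_size from the
  manifest (default 0.5 μm/px — an explicit package choice, as such
  instruments vary). `aspect_ratio` = √(λ₂/λ₁) of the pixel-coordinate
  covariance (+1/12 px² diagonal for finite pixel size), i.e. the
  minor/major axis ratio of the equal-second-moment ellipse; defined as 1
  for degenerate masks.
- `gradient_rms`: RMS central-difference gradient magnitude over the mask;
  `contrast`: (p95 − p5)/(p95 + p5 + 1e−6) of raw mask pixels. Both are
  focus metrics.
- `spot_count` (γH2AX): white top-hat with a disk of radius 3 px removes the
  smooth nuclear background; pixels above median + k·(1.4826·MAD) of the
  in-nucleus top-hat values (k = 4) are candidates; connected components
  ≥ 3 px are spots. The threshold is centered on the median (robust
  z-score); without centering, read noise alone produces spurious 2-px
  detections in ~1% of nuclei. The 3-px area floor removes adjacent
  noise-pixel pairs while true rendered foci span ~20 px. Touching foci
  merge into one spot — no watershed splitting, by design (deterministic,
  and an intentional, documented bias at high focus densities).
- `dapi_area_um2` / `dapi_intensity` are computed over **all** DAPI
  components (not just the largest), so a doublet's two nuclei double both.

Missing channels yield missing features (NaN), never zeros.

## Gating

Gates are declarative (YAML or dicts): threshold, interval, 2-D rectangle,
and boolean (AND/OR/NOT) over previously defined gates, each with an
optional parent. Evaluation is in declaration order; child membership is
intersected with the parent, so hierarchy containment holds exactly. Cells
missing a required feature drop out of that gate and are tallied as
"ungated".

Thresholds for stain positivity come from control samples: the cutoff is a
linear-interpolation quantile of the control cells that pass the gate's
parent. Defaults: 0.01 "below" for SA-β-gal darkness on `bf_mean_pixel`,
0.99 "above" for fluorescence positivity. By construction the control gates
~1% of itself positive — a deliberate, visible false-positive floor. Where a
low-prevalence SA⁺ subset feeds conditional statistics (the
proliferation-marker overlap recipe), that floor would contaminate the
conditional, so the preset uses a fixed manual cutoff placed in the valley
between the unstained and stained BF modes — the equivalent of a visually
verified gate; the modes are many standard deviations apart, so placement
is not critical.

Singlet gating: in vitro, a rectangle on BF area (50–5000 μm²) and aspect
ratio (≥ 0.6) — tangent-cell doublets are elongated. In dissociated-tissue
scenarios, a rectangle on DAPI area and total intensity in **multiples of
the sample median** (defaults 0.3–3.0× area, 0.45–1.6× intensity): total
DAPI intensity tracks DNA content, so two nuclei ≈ 2× intensity, while a
large senescent nucleus keeps ~1× and passes. Focus gating thresholds
`gradient_rms` and `contrast` (defaults 3.5 and 0.005, frozen from synthetic
calibration at default noise). Read noise survives defocus, so the gradient
metric has a noise floor; for very large, weakly contrasted fibroblasts the
in-vitro presets lower the floor to 2.0, where the gate only removes
degenerate frames. Defocused cells are phenotype-independent in the
generator, so their retention does not bias percentages.

Population statistics: percent positive per sample (with n_parent/n_gate),
mean ± SEM across samples, and mean area ± SEM inside vs outside a gate
within the same parent (the SA⁺-vs-SA⁻ size comparison). Group comparison is
the classic equal-variance two-tailed t-test (`scipy.stats.ttest_ind`). No
multiple-testing correction is applied; percentages are reported raw.

## Synthetic generator

Each sample (population) draws per cell: a cell type (categorical, with
per-type senescent-fraction/area/channel overrides); a latent senescent
state; an X-gal staining state conditional on it (sensitivity, default 1.0;
false rate, default 0); marker positivity conditional on senescence; a focus
count (positives: min 3 + Poisson(3); negatives: Poisson(0.3)); a lognormal
target area; DNA content (lognormal, CV 0.1); viability; and nuisance
states (doublet, defocus; defaults 2% each in the presets).

Rendering: cells are soft-edged ellipses (aspect drawn in [0.8, 1.0], linear
edge ramp 15% of the radius, so the half-height mask contour sits at the
target radius); BF = background (600) − darkness × cell profile, where
darkness = a baseline attenuation every cell shows (N(30, 5), making
unstained cells visible in BF as on a real instrument) plus, if stained, a
shift N(180, 15). The nucleus (22% of cell area) carries DAPI with **total**
intensity 5×10⁴ × DNA content (independent of nuclear size), Gaussian γH2AX
foci (σ 1.5 px, amplitude 40, dart-throwing placement with best-effort 6-px
separation) over a faint haze, and nuclear marker levels (lognormal;
positive mean 80, negative/autofluorescence 4). Cell-type channels and the
viability dye fill the whole cell profile. Doublets add a tangent clone;
defocus is a σ = 6 px Gaussian blur; finally Gaussian read noise (σ = 2) is
added and pixels are rounded to integers (lossless uint16 round-trip).
(config, seed) determines every pixel: phenotypes and each cell's render use
independent counter-derived RNG streams, so generation order or laziness
cannot change the data.

What the generator does **not** emulate: real X-gal granularity and
perinuclear localization, autofluorescence spectra and spillover between
channels, cell-shape irregularity beyond ellipses, debris and acquisition
artifacts, density-dependent staining. Passing end-to-end tests therefore
demonstrates that the measurement and gating chain is correct and unbiased
under the stated noise model — not that the defaults are transferable to any
particular instrument; singlet/focus/positivity parameters are config keys
for that reason.

## Preset scenarios and problem sizes

Six presets encode the standard study designs with their published
population values as injected truth: etoposide-senescent vs growing
fibroblasts (SA⁺ 89.6% vs 4.8%; γH2AX⁺ 28.3% vs 7.8%; areas 668.9 vs
461 μm²), the SA⁺∧HMGB1⁻ two-marker call (86.8% vs 3.88% joint), p53
restoration in GFP⁺ tumor cells (69.8% vs 2.4%, with viability and CD45
gating), bleomycin-fibrotic lung by compartment (epithelial 8.96% vs 1.14%;
immune 15.3% vs 16.11%), proliferation-marker overlap (Ki67⁻∧BrdU⁻ in
95–97% of SA⁺ and ~5.6% of SA⁻ cells; the two marker conditionals are
modeled independent given senescence), and adipose stromal cells in aging
(13.8% vs 1.4%, with senescent cells rendered larger). Where a study value
is shown only graphically (immune-cell percentages in the tumor model, the
absolute size means in vivo) the preset documents its own choice.

Presets ship 400–1,400 cells per population; the acceptance script scales
them ×1.5 and averages two derived seeds per scenario (≈ 25k cells total,
a few minutes on one CPU), keeping binomial standard errors under ~1
percentage point. The test suite uses 600–800 stained cells per population.
Recovered percentages carry the ~1% control-quantile false-positive floor
and binomial noise; mean areas are unbiased within ~1%.

## Numerical conventions

Quantiles/percentiles: numpy linear interpolation. Images: uint16 on disk,
float64 in memory; pixel centers on integer coordinates; areas in pixel
counts × pixel_size². Aspect ratio of a <2-pixel mask is 1.0. Background of
a full-frame mask falls back to the image border. Empty masks, absent
channels, cyclic or ill-ordered gate trees, and <50 control values raise
typed errors before any statistic is produced.

## Known limitations

- Merged foci undercount at high focus density (no watershed).
- The DAPI singlet gate assumes near-constant DNA content; S/G2-phase
  enrichment would be partially excluded as pseudo-doublets.
- Control-referenced gates inherit a (1 − quantile) false-positive floor;
  at very low prevalence, prefer a manual valley cutoff (as the
  proliferation-overlap preset does).
- One cell per record is assumed; fields with many touching cells need
  upstream detection/cropping.
- The focus gate cannot separate defocused from in-focus cells whose edges
  are weaker than the read-noise gradient floor (large unstained
  fibroblasts).
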