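# Methods

## Scope and model

`tissuescore` implements a digital PD-L1 (22C3) assay for brightfield IHC
images at desk scale (single-field RGB rasters up to ~4000×4000 px,
default 0.5 µm/px emulating 20X scans). Whole-slide pyramidal formats are
out of scope; `read_slide_image` is the documented extension point for a
WSI adapter. The pipeline is: image quality gate → color deconvolution →
nucleus detection → cell feature extraction → tumor/stroma compartment
assignment → per-cell PD-L1 positivity → TPS; optionally immune-cell
classification before the TPS denominator is formed.

## Optical-density model and stain separation

Pixels are converted to optical density per channel as
`OD = -log10((p + 1)/256)`, under which stain contributions add
(Beer–Lambert). The image OD is decomposed onto the published
hematoxylin/DAB basis (the H-DAB matrix shipped with scikit-image,
rows unit-normalized; the third row completes the frame). Hematoxylin and
DAB planes are clipped at zero (stain amounts are physical); the residual
plane is a signed remainder and is left unclipped so that the three
planes reconstruct the measured OD exactly. The synthetic renderer
composes images through the same basis, which makes deconvolution exactly
invertible at zero noise up to 8-bit quantization (~2×10⁻³ OD per
channel) — the basis of several analytic test oracles.

## Cell detection and features

Nuclei are segmented on the hematoxylin plane: Gaussian smoothing
(σ = 1 px), a fixed OD threshold (0.25), a distance-transform watershed to
split touching nuclei (seed separation 3 px), then area (8–900 px²) and
solidity (≥ 0.6) filters. Around each nucleus a membrane ring (dilation by
2 px, clipped against neighbors by a label-constrained partition) and a
cytoplasm annulus (3 px further) are built. The fixed-order feature
vector per cell: nucleus area, equivalent diameter, eccentricity,
solidity, mean/variance of nuclear hematoxylin OD, mean and p90 of
membrane-ring DAB OD, mean cytoplasm DAB OD, ring completeness, and local
cell density (neighbors within 25 px). Models store a hash of this column
order and refuse to predict against a different layout.

Membrane intensity is summarized by the ring p90 rather than the mean:
partial rings (clipped by neighbors or image borders) then still reflect
the stained arc. Positivity cut points t1 < t2 < t3 on ring p90 DAB OD
map to ordinal grades 0/1+/2+/3+ with a half-open convention (an OD
exactly at a cut lands in the higher grade). The defaults
(0.175, 0.45, 0.75) are the midpoints between the renderer's grade
anchors (below) and are frozen in config — once finalized, thresholds do
not change across a validation study.

## Tumor/stroma separation and annotations

Cells inside analyst-circled `train_tumor` / `train_stroma` polygons form
the labeled training set (centroid-based point-in-polygon, strictly
inside on the boundary; cells in `exclude` polygons are dropped — the
precedence order exclude > train > include is total). The default
classifier is a 100-tree random forest (seeded, single-threaded);
`extra_trees` and `logistic` are config switches. Held-out accuracy is
estimated on a stratified 25% split before refitting on all labeled
cells. At assignment time, cells outside every inclusion polygon or
inside any exclusion polygon are `excluded`; "viable tumor cells" is
realized purely through exclusion annotations (necrosis, artifacts),
not per-cell viability calling.

## TPS

TPS = 100 × positives/denominator over tumor-compartment cells, reported
with the therapy bins <1 / ≥1 / ≥50%. Two denominator policies exist:
`raw` (every tumor-compartment cell — the class-agnostic count) and
`immune_corrected` (cells predicted macrophage/lymphocyte removed, so
only tumor cells are counted). A zero denominator flags the result
unscorable rather than raising. Inference is deterministic end to end —
seeds exist only in training and simulation — so repeated scoring of one
image has exactly zero variance.

## Immune-cell recognition

Dual-IF images (CD68/CD163 for macrophages, CD3/CD20 for lymphocytes) of
the same cell population are co-registered to the brightfield image by a
two-stage rigid fit: coarse translation from FFT cross-correlation of
Gaussian-smoothed blob/cell density maps (search bounded to ~10% of the
image extent), then trimmed iterative-closest-point refinement with a
Kabsch fit per iteration; the transform is reported about the image
center with its mean matched-point residual, and residuals above 2 px
raise an error. Brightfield cells are paired to IF blobs by
mutual-nearest-neighbor within 5 px; a cell matched to a blob carrying
either panel marker is labeled positive for that panel, all others
negative. IF blob positivity uses a fixed amplitude threshold (0.25 over
a ~0.02 background) after 1 px smoothing; the union count across the two
channels de-duplicates double-positive cells within 4 px.

Candidate families (random forest, scaled logistic regression) are each
fitted on the transferred labels and scored on a disjoint verification
set by mean absolute percent error between predicted and known counts;
the lowest error wins (ties break alphabetically, deterministically).
Both immune classes use the same IF label-transfer path; the
tissue-vs-alveolar macrophage subtype head is trained on generator truth
labels instead, because CD68/CD163 positivity cannot distinguish the
subtypes — morphology (size, context) carries that signal. Immune
prediction never modifies a cell's PD-L1 bin, so PD-L1± immune tallies
stay consistent with the intensity calls.

## Validation statistics

Cell-level metrics match predictions to ground truth mutual-nearest-
neighbor within 5 px: identification rate (matched truth fraction), false
positive rate (truly negative matched cells called positive) and false
negative rate (truly positive called negative), with per-sample criteria
≥ 90% / ≤ 10% / ≤ 20% and a cohort pass when ≥ 90% of samples meet them.
Accuracy concordance is the fraction of samples whose digital and manual
TPS fall on the same side of the 1% treatment cut-off (pass ≥ 90%).

Precision uses the ICC from a balanced two-way (sample × repeat)
method-of-moments variance decomposition: σ²-components for sample,
repeat (day) and residual, negative moment estimates truncated at zero,
proportions normalized to sum to 1, and
ICC = 1 − (repeat + residual proportions) — equal to the sample
proportion and numerically identical to the two-way random
absolute-agreement ICC(A,1) (cross-checked against pingouin in tests).
The wording "variance attributable to inter-sample variability and
residual error" suggests the variant 1 − repeat-proportion; both are
computed (`icc` and `icc_prose`), the subtraction form being primary.
Components below 10⁻¹² of the largest are flushed to exact zero so
bit-identical repeat columns give ICC exactly 1. The 95% CI comes from
≥ 1000 parametric simulations at the observed design (same sample and
repeat counts) with refitting per replicate and percentile 2.5/97.5
bounds; the design is fixed at the observed one. Reliability categories:
< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent; a
precision pass needs point estimate and CI lower bound ≥ 0.6.

Concordance uses Pearson's r with two-sided p-values; the Bonferroni
threshold is family-alpha/n exactly (0.05/3 reported as 0.017, rounding
never affects decisions). Average percent error is
mean(100 × (predicted − truth)/truth), negative meaning under-prediction;
zero-truth samples are excluded with a warning.

## Synthetic slides: what they emulate and what they do not

The generator renders, in OD space, hematoxylin-stained nuclei and DAB
membrane rings on a faint tissue background, with per-pixel Gaussian OD
noise (default sd 0.05). Grades map to fixed mean membrane ODs — 0→0.05,
1+→0.3, 2+→0.6, 3+→0.9 — since the 1+/2+/3+ scale has no published
numeric definition. Tumor cells (nucleus radius 5.0–6.5 px) sit on
jittered grids inside circular nests; stromal fibroblast-like cells
(3.5–4.5 px, elongated) outside; lymphocytes (2.4–3.2 px, dense
chromatin) and tissue macrophages (6.5–8 px) are split between stroma and
nest interiors; alveolar macrophages (8–9.5 px) occupy the airspace
annulus just outside nest borders and belong to the tumor compartment.
Immune cells carry membrane-plus-cytoplasm DAB, tumor cells membrane
only. Placement spacing is chosen so neighboring membrane rings do not
overlap; a canvas that cannot hold the requested counts raises an
explicit density error. Exactly round(true_tps/100 × n_tumor) tumor cells
are positive; immune cells are positive at an independent rate (default
0.3). Cohort TPS values have no published distribution, so studies draw
them uniformly over 0–95 unless a grid is requested.

IF pairs are two-channel float rasters with Gaussian blobs (σ 2.5 px) at
marker-bearing cells, displaced by a recorded rigid transform — the
registration oracle. Serial sections share one cell population with
per-section positional jitter (and 1% dropout when jitter > 0); zero
jitter reproduces identical sections. Simulated readers score
clip(truth + bias + reader offset + read noise, 0, 100) with defaults
(bias 0, between-read sd 2, per-reader sd 1, 3 readers × 3 reads)
representing a competent, nearly unbiased reader panel.

Deliberately absent: nuclear texture, photorealistic histology, staining
gradients, tissue folds, out-of-focus regions, cell-shape irregularity
beyond ellipses. Passing tests therefore demonstrate the correctness of
the measurement and statistics chain under the stated noise model — not
segmentation robustness on real tissue, where touching cells, texture
and artifacts dominate the error budget.

## Study sizes and numerical choices

The shipped studies use 512×512 slides with ~470 cells (250 tumor): a
20-slide cohort for cell-level criteria, 5 training + 2 verification
slides and a 30-sample cohort for immune accuracy, 20 samples × 3 serial
sections (1000-simulation CI) for immune precision, and a 21-slide TPS
sweep (0–95 in steps of 5 plus an all-positive slide) for the reportable
range — sizes chosen so a full validation runs in minutes on one core
while keeping every criterion's sample size at or above its stated
minimum. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); scikit-learn estimators are seeded and
single-threaded, so every artifact is bit-reproducible.

## Known limitations

- Compartment classification is cell-wise, not region-wise; isolated
  tumor-like cells in stroma can be mis-assigned (mitigated by local
  density as a feature).
- The `raw` TPS denominator includes intratumoral immune cells, diluting
  high scores by a few points on immune-rich slides; `immune_corrected`
  addresses this but depends on immune-classifier quality.
- Registration assumes a rigid transform with bounded offset; serial
  sections with real tissue deformation would need a non-rigid model.
- QC thresholds (focus variance-of-Laplacian ≥ 3, blank-tile fraction
  ≤ 0.30, saturation ≤ 0.30) are calibrated on synthetic fixtures; real
  scanners need recalibration.
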