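# Methods

`ifcprofiler` analyzes imaging-flow-cytometry (IFC) records of T-cell /
B-cell conjugates: multichannel single-cell images (brightfield, F-actin,
MHCII, CD3, phosphorylated CD3ζ, optionally a viability stain) with
per-channel segmentation masks. The pipeline classifies each record into
one of nine conjugate classes, cleans the predictions, and profiles how an
antibody treatment shifts class frequencies and synapse morphology, ending
in a sparse linear model that predicts a per-donor functional readout from
aggregated synapse features. This note records the model choices, the
defaults and why, and what the synthetic data generator does and does not
emulate.

## Record model and splits

A record is one event: a `C x H x W` uint16 intensity stack plus boolean
masks and metadata (donor, experiment, condition, optional expert label),
stored one per HDF5 file (`image`, `masks`, `channels` datasets, a `meta`
attribute group) so cohorts parallelize trivially. Masks are boolean,
row-major `(y, x)`, `True` = inside cell. Optional fields (label, class
probabilities) are stored only when present.

The stratified splitter allocates `floor(f * n_c)` training records per
class and distributes the remaining slots — up to a train total of
`floor(f * n)` — by largest fractional part, ties broken by class name.
Every per-class train count is therefore within one record of exact
proportionality; 5,221 labeled records at 70 % give 3,654/1,567. An
epsilon (1e-9) guards the floor against binary-float artifacts such as
`0.7 * 5220 -> 3653.999…`.

## Feature families

All features are computed from the masked intensities and mask geometry;
missing values are explicit NaN (never silently 0), with one documented
exception below.

* **Morphology (30 per mask):** 16 scalar descriptors (area, bounding-box /
  convex / filled area, eccentricity, equivalent diameter, Euler number,
  extent, max/min Feret diameter, major/minor axis, orientation, perimeter,
  Crofton perimeter, solidity), 7 Hu moments and 7 intensity-weighted Hu
  moments. Multi-cell masks are treated as one (possibly disconnected)
  region, so e.g. the Euler number counts components minus holes. The
  minimum Feret diameter is the exact minimum caliper width of the
  pixel-corner convex hull (rotating-calipers over hull edges); the rest
  come from `skimage.measure.regionprops`.
* **Intensity (17 per channel):** min, max, sum, mean, sd, skewness,
  kurtosis, Shannon entropy, and the 10th–90th deciles, over masked pixels
  only. Percentiles interpolate linearly between closest ranks. Entropy
  uses a 256-bin histogram of the 16-bit range rescaled to [0, 1], natural
  log. Skewness/kurtosis of a constant region are defined as 0.
* **Texture (6 per channel):** GLCM contrast, dissimilarity, homogeneity,
  ASM, energy, correlation. Masked intensities are min-max rescaled and
  quantized to 32 levels; out-of-mask pixels get a reserved level whose
  rows/columns are discarded so co-occurrences never cross the mask edge;
  distance 1, four angles, symmetric, per-angle normalized then averaged.
  Correlation of a zero-variance matrix is defined as 1.
* **Co-localization (17 per unordered channel pair):** Dice and Jaccard
  distances, intersection/union areas and intersection-over-min-area from
  the masks; correlation, Euclidean and cosine distances, Pearson and
  Spearman correlation and a 16x16-bin mutual information over the
  union-of-masks pixel set; Manders M1/M2 and the overlap coefficient;
  intensity correlation quotient (fraction of union pixels whose
  deviations co-vary, minus 1/2); full-frame structural similarity; and
  the symmetric Hausdorff distance between mask point sets.
* **Synaptic (3 per channel):** the synapse mask is the intersection of
  the T-cell (CD3, or a substitute such as CD4) and B-cell (MHCII) masks
  after each is dilated by a disk of radius 3. Intersection — not union —
  because the contact zone is where enrichment is biologically meaningful;
  a union would cover both cells and pin the ratio near 1 by construction.
  Enrichment (mean) = mean intensity in the synapse / mean in the cell
  mask; (sum) uses sums; (max) divides the synapse maximum by the cell
  mean. An empty synapse mask is a real "no contact" measurement and yields
  0 for all three (the exception to NaN-for-missing); a zero denominator
  yields NaN.
* **Quality control (2 per channel):** background mean (outside the union
  of all masks) and the RMS Sobel gradient magnitude within the channel's
  mask — a focus measure. The vendor software's gradient-RMS definition is
  not public; the Sobel-RMS form is this package's own.

The *fluorescent-relevant* preset is 27 features per channel (17 intensity
+ 6 texture + 3 synaptic + mask area) plus 17 per pair: 210 columns for a
four-fluorochrome panel and 132 for three. These two counts uniquely
determine the per-channel/per-pair decomposition; the *full* inventory
(adds brightfield morphology, viability intensities and QC) is
configurable and makes no claim to a fixed total.

## Feature pre-selection

Median imputation, then three stages, all seeded: (1) greedy elimination
of near-duplicates — features are visited in random order and any
not-yet-visited feature with |Pearson| > 0.95 to a kept one is dropped;
(2) six rankings (k-NN mutual information, linear-SVM weights, L1- and
L2-logistic coefficients, random-forest importance, gradient-boosting
gain; linear models on standardized features, ties broken by name) whose
top-k union forms the candidate set; (3) spectral clustering of the
candidates on |Spearman| affinity into m clusters, keeping one random
feature per cluster to break residual multicollinearity. Defaults k = 50,
m = 50; both are tunable. Note the last stage deliberately collapses a
group of mutually correlated informative features to a single
representative — that is its purpose, not a loss of signal.

## Classification and explainability

Five classifiers sit behind one registry: logistic regression, LDA,
linear SVM, random forest, and gradient boosting (XGBoost, 100 trees —
the reference configuration). Evaluation is stratified 5-fold
cross-validation with 10 repetitions (50 scores, mean ± sd of macro-F1)
and leave-one-donor-out CV for donor generalization. Imputation and any
pre-selection are refit inside each training fold; doing otherwise leaks
test information. Macro-F1 averages per-class F1 over the classes present
in either the truth or the prediction. No class reweighting is applied
(plain macro-F1 is the reported metric); a switch exists.

Feature importance is the in-model *gain*: for each feature, the summed
loss improvements of all splits using it divided by the number of those
splits, normalized to sum to 1; unused features score 0. The stability
protocol retrains 5 folds x 100 repeats = 500 models, each with a
pre-selection size top-k drawn uniformly from [30, 200], and ranks
features by their median gain across the models where they were available.
Channel ablation keeps the stain-free brightfield channel and evaluates
every non-empty fluorochrome subset (15 for a four-stain panel); features
are extracted once on the full panel and column-filtered per subset, which
is equivalent to rebuilding the inventory because every feature references
only its own channels. SHAP-style post-hoc explanation is out of scope; the
model artifacts expose the fitted booster for external tools.

## Cleaning

Nine rules run per donor x condition sample, in order, with first-match
attribution (so per-rule removal sets are disjoint and retained + removed
= input). All percentile thresholds are computed on the sample being
cleaned and frozen before any rule fires: (1) mean viability >= its 90th
percentile; (2) brightfield gradient RMS not strictly inside its
2nd–90th percentile band; (3) prediction entropy > 1.0 nat; (4–5)
predicted B-LCLs with mean MHCII < 5th percentile or MHCII area < 10th;
(6) predicted single T cells with mean CD3 < 1st percentile; (7) predicted
one-layer conjugates with MHCII area < 20th percentile; (8) isolation
forest (100 trees, auto subsampling/contamination, 20 features per split)
on the top-30 gain features; (9) standardize the top-30 features, embed to
2-D with UMAP (15 neighbors, min-dist 0.1, seeded), cluster with DBSCAN
(eps 0.09, min_samples 5), and remove noise points and clusters with
frequency < 1e-4.

Two calibration notes. First, rules whose threshold is a percentile of
the very sample they filter always remove the corresponding quantile mass
(rule 1 removes the top decile of any sample); that is inherent to the
protocol. Second, the DBSCAN eps is density-dependent: 0.09 presumes
samples of ~5x10^4 records, where the 2-D embedding is dense. On small
cohorts that eps marks most points as noise, so the pipeline configuration
exposes it and desk-scale runs should use a larger value. Removing
unclustered noise points along with rare clusters is this package's
choice where the protocol names only the cluster-frequency cut.

## Population profiling

Class frequencies are computed per donor x condition over the seven
non-artifact classes ('T cell w/ small B-LCL' and 'no cell-cell
interaction' are annotation artifacts, excluded from numerator and
denominator). Antibody vs control is summarized per class by the
per-donor log2 fold change of frequencies; zero frequencies leave the cell
undefined rather than pseudo-counted. Because the design is donor-paired
(the same 6–7 donors measured under both arms), significance uses the
one-sample exact Wilcoxon signed-rank of the log2FCs against zero —
enumerating all 2^n sign patterns of the mid-ranked |log2FC| for n <= 12 —
followed by Benjamini-Hochberg across the seven classes. With six donors
all moving one way this yields p = 2/64 = 0.03125, and BH with one
non-significant class lifts the six to 0.03125 x 7/6 ≈ 0.036; with seven
donors, 2/128 x 8/7 ≈ 0.022. A two-sample rank-sum variant is available
for the unpaired reading of the protocol.

Feature differences restrict to records predicted as signaling synapses
and compare each feature between arms per donor with a two-sided
Mann-Whitney U — full enumeration of the C(n+m, n) group assignments when
both arms have <= 8 records (exact under ties), otherwise the
tie-corrected normal approximation with continuity correction. BH is
applied across features *within* each donor (the family a per-donor column
of the difference map represents), and each cell is coded +1/-1 only when
the adjusted p < 0.05, signed by the median difference. The cross-donor
consistency count (same nonzero sign in >= k donors) defines the
reproducible signature passed to the regression stage.

## Functional regression

The functional readout (e.g. % Granzyme-B-positive T cells) exists once
per donor x condition; images are many. Records predicted as synapses
(with or without signaling) are pooled per donor x condition and each
feature is aggregated by its 5th, 50th and 95th percentile — extremes and
average — giving 3 columns per feature. A LassoLars model is trained
under leave-one-donor-out (or condition-rotation) cross-validation:
columns are standardized on the training rows only, the L1 strength is
chosen by inner leave-one-out over the LARS path (the row counts are far
too small for a fixed alpha to be defensible; an override exists), and
pooled held-out predictions are summarized by Spearman rank correlation.
Importance is the |coefficient| ordering on the standardized scale;
unstandardized coefficients are also reported and match planted
generative coefficients exactly in the noise-free case.

## Synthetic data generator

The generator renders 64x64, 5-channel (+ viability) records from
disk-shaped cells: T cells carry CD3 (radius ~8 px), B-LCLs carry MHCII
(~11 px), every cell carries F-actin and brightfield signal. The nine
classes differ in composition and geometry: singlets are lone disks
(with or without P-CD3ζ signal); 'T cell w/ small B-LCL' attaches a
undersized B disk; 'one layer' overlaps the disks heavily; synapses touch
with a small contact zone; 'no cell-cell interaction' separates the cells
beyond the dilation reach of the synapse mask; multi-synapses chain 3–4
alternating cells. At functional synapses, F-actin, MHCII and P-CD3ζ are
multiplied at the contact interface by enrichment factors rho (defaults
2.0 / 1.5 / 2.5) — painted across the whole interface, which straddles
both cell bodies, as synaptic accumulation does. Signal means (~2,000–
3,000 counts on a background of 100) receive Poisson noise plus additive
Gaussian read noise (sd 50); defocus fixtures add a Gaussian blur; dead-
cell fixtures draw the viability channel from a high-intensity component.

Cohorts add: a per-donor log-normal gain (sd 0.15) shared across channels
— a donor random effect; per-condition class-frequency simplexes (the
planted log2FC structure); per-condition channel gain factors, whose
ground-truth feature directions are the 14 scale-equivariant intensity
statistics per channel; and a linear functional readout over aggregated
features with chosen coefficients and noise.

What the generator does **not** emulate: realistic cell texture and
sub-cellular structure, the point-spread function, spectral spillover,
segmentation errors, or the absolute intensity distributions of a real
cytometer. Passing tests therefore demonstrate that the pipeline's
statistics recover planted structure through real image rendering and
feature extraction — not that the classifier's 0.99 macro-F1 on synthetic
disks predicts the ~0.92 achievable on real conjugates, where class
boundaries are genuinely ambiguous.

## Problem sizes and numerical choices

The benchmark suite uses a 2,700-record nine-class cohort (3 donors x 900
records) for the repeated-CV benchmark, 6 donors x 2 arms x 300 records
for shift recovery, and 8 donors x 4 conditions for functional recovery —
sizes at which every planted effect is comfortably powered on one CPU.
Exact tests switch to their tie-corrected normal approximations beyond
n = 12 (signed-rank) / 8 per arm (Mann-Whitney). Seeds derive from one
global seed per stage via a CRC-based scheme, all below 2^31; worker count
never changes results (rows are keyed by record id and reassembled in
input order).

## Known limitations

* Morphology of a multiplet is described by whole-mask properties, not
  per-cell instance properties (segmentation of individuals is upstream).
* The full feature inventory is configurable; no fixed grand total is
  claimed or needed by any analysis.
* The embedding-based cleaning rule requires density calibration (see
  above) and is the only stage whose behavior depends qualitatively on
  sample size.
* Structural similarity is computed full-frame with a data-range taken
  from the two images, so it is meaningful for comparisons within a
  cohort rather than as an absolute calibrated index.
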