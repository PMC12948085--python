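# Methods

This note documents the models, the statistical choices behind them, the
synthetic data they are validated on, and the package's known limitations.

## Differential expression

The screen compares all responder cells against all non-responder cells,
pooled across samples and timepoints, gene by gene, with the two-sided
Wilcoxon rank-sum test: exact enumeration when both groups have ≤ 10
observations and no ties, otherwise the normal approximation with
tie-corrected variance and continuity correction. Identical groups are
assigned p = 1 (any convention ≥ α would do; 1 is the conservative choice).
P-values are Benjamini–Hochberg adjusted.

Fold change is reported as

    log2FC = log2[(mean(2^x − 1) + 1)_A / (mean(2^x − 1) + 1)_B],

the de-logged group-mean ratio with pseudocount 1 used by the mainstream
single-cell toolkits; a plain difference of log-means is available via
`fc_method="logdiff"`. Global mode flags |log2FC| > 1 with adjusted
p < 0.05; marker mode pre-filters to genes detected in ≥ 10% of either
group with |log2FC| ≥ 0.25 before testing. An optional global prevalence
filter (`min_pct`) exists but defaults to off, so the global screen tests
every gene.

Cell-level pooling treats cells of one patient as independent, which they
are not; this pseudoreplication inflates cell-level significance and is the
reason the model benchmark offers a patient-level split (below).

**Module scores** follow the binned-control construction: genes are placed
into `n_bins` (default 24) equal-frequency bins by dataset-average
expression; for each set gene, `n_ctrl` (default 100) control genes are
sampled from its bin (without replacement when the bin allows) and pooled;
the score is mean(set) − mean(controls) per cell. The control pool may
legitimately contain other set genes (faithful to the reference
construction), which shrinks recovered shifts slightly when sets are large
relative to bins. A random set scores 0 in expectation.

**Bimodal markers** are split with a two-component Gaussian mixture
(5 restarts, seeded); the threshold is the equal-posterior point between
the component means, found on a 2001-point grid. The separability
diagnostic is (μ_high − μ_low)/pooled SD; fits with diagnostic < 1 are
returned flagged low-confidence rather than rejected.

## Gene-level benchmark

Default split: stratified 80/20 at the **cell** level with seed 42,
matching the protocol the package reimplements. Because cells of one
patient land on both sides of a cell-level split, a `unit="patient"`
mode assigns whole patients to a partition; on synthetic cohorts with
nonzero per-sample intercepts the patient split yields lower (honest) AUCs,
and the test suite checks that ordering in expectation. Feature z-scoring
is fitted on the training partition only by default; a pooled
(protocol-faithful, leakage-prone) mode exists behind a flag and is logged
loudly when used.

Models: XGBoost, random forest, logistic regression, RBF-SVM, a
feed-forward network, and a 1-D CNN over the DEG axis. All but logistic
regression are tuned by randomized search over package-default spaces with
stratified 5-fold cross-validation scored by ROC-AUC, then refit on the
full training partition. The FNN is a (64, 32) ReLU multilayer perceptron
with L2 regularization searched alongside its width — L2 rather than
dropout so the model participates in the same sklearn search machinery as
its peers. The gene 1-D CNN has two conv blocks (conv → ReLU → batch norm →
max-pool 2 → dropout 0.3; 32 and 64 filters, kernel 5 — widths are package
defaults, the block structure is fixed) and trains with Adam at 1e-3,
binary cross-entropy, up to 100 epochs with early stopping after 5
non-improving validation epochs.

Tree importances are gain-based for boosting and impurity-decrease for the
forest, ranked descending with average ranks for ties. **Concordant genes**
are the intersection of the two top-`n` sets (default n = 50 — the simplest
operator consistent with "consistently important in both rankings"),
ordered by mean rank, reported with the Spearman correlation of the full
rank vectors. The stability study refits the tuned settings on `n_splits`
(default 100) fresh stratified splits and reports percentile 95% CIs and
the rank correlation of mean resampled AUC with the original single-split
AUCs.

## Pathway-level models and attribution

Two encodings of the same information: the **pair matrix** (one column per
unique (gene, pathway) membership, valued at the gene's expression) and the
per-cell **gene × pathway image** (entry (g, p) = expression of g if
g ∈ p else 0). A property test asserts the two encodings carry identical
nonzero (gene, pathway, value) triples. Image ordering — pathways in
collection order, genes by first-containing pathway then symbol — is
deterministic and recorded in a legend, because convolutional locality
depends on it; results of the 2-D model are in principle
ordering-sensitive, which is surfaced rather than hidden.

Architectures (all trained with Adam at 1e-4, binary cross-entropy, batch
64, up to 30 epochs, early stopping patience 3, checkpoint restored at best
validation accuracy; validation is a stratified 10% carve-out of the
training partition):

* pathway 1-D CNN: conv blocks of 128×k15, 64×k15, 32×k5 (each conv → ReLU
  → dropout 0.3 → max-pool 2), flatten, dense 64, sigmoid; standardized
  pair vectors in.
* pathway 2-D CNN: conv 128@3×3 'same' → ReLU → dropout → 2×2 pool,
  conv 64@3×3 → ReLU → dropout → 2×2 pool, global max pool, dense 64,
  sigmoid. Images stay on the raw log2 scale — per-pixel standardization
  would destroy the structural zeros that carry the membership pattern.

These networks (and Grad-CAM) run on an in-package numpy core with manual
backpropagation (`scresponse.nn`); gradients are validated against central
finite differences, and training is bit-deterministic given its seeds.
Weights are float32 by default (float64 for the gradient-check tests).

**Grad-CAM**: channel weights are the spatial means of the class-score
gradient at the final conv activation (class score = logit for the
responder class, −logit for the non-responder class); the map is the
rectified weighted sum of activation channels, bilinearly upsampled to
image resolution (nearest-neighbour available). Maps are rectified per the
original Grad-CAM definition. Per-class maps average every cell of the
class at its own class index (a flag restricts to correctly classified
cells); the difference map is responder mean − non-responder mean. Note
that with rectified per-class maps the difference is *not* antisymmetric
under label swap — ReLU(−S) ≠ −ReLU(S) — so the difference map should be
read as "where each class's own evidence lives", not as a signed symmetric
contrast.

**Spot extraction** thresholds the positive entries of the difference map
at quantile `q`, labels 4-connected components, ranks them by summed
absolute mass, and reports the top spot per sign with its spanned gene and
pathway lists. `q` is scale-dependent by geometry: the above-threshold area
should be comparable to the expected spot area. At full scale
(383 × 186 grid, 64 × 8 spot ≈ 0.7% of cells) q = 0.99 is appropriate and
is the library default; the reduced CI profile (48-row × 12-column grid,
16 × 4 block ≈ 11% of cells, about a fifth of the positive entries) uses
q = 0.8 for the same reason.

## Signature scoring and survival

The rank signature score ranks all n genes within each bulk sample
(ascending, average ranks for ties) and normalizes the mean rank of the k
set genes to [0, 1] against its theoretical bounds ((k+1)/2 and
n − (k−1)/2). It is invariant to any strictly increasing transform of a
sample's expression. Only the up-set variant is implemented — the
signatures scored here are single responder-specific gene lists with no
down component.

Scores are dichotomized at the median by default (the cut is always
reported; a quantile is configurable). Kaplan–Meier estimation and the
log-rank test come from lifelines; univariate Cox regression uses the
Breslow tie convention (simpler than Efron and adequate at the tie
densities simulated) via statsmodels, with non-convergence (monotone
separation) raised as an explicit error.

## The synthetic cohort

Per gene, a baseline log2 mean is drawn from Gamma(2, 0.7) (right-skewed,
mean ≈ 1.4, resembling the low, skewed log2(TPM+1) profile of
plate-based single-cell data). Per cell, expression = max(0, baseline +
class effect + sample intercept + N(0, 0.9)), then zeroed with probability
0.3 (dropout). Planted DEGs receive a +1.5 log2 shift in their class (86 up
in responders, 124 up in non-responders at the default scale). Sample
intercepts are N(0, 0.2) scalars shared by all genes of a sample — enough
patient-level structure to make cell-level and patient-level splits
distinguishable. One bimodal marker (modes 0.5 and 4.5, SD 0.5, high mode
in 70% of non-responder vs 25% of responder cells) emulates a
mixture-expressed gene; dropout is not applied to it so its two-mode shape
stays clean for the mixture-fit tests.

Pathway sets plant one responder and one non-responder spot: spot genes are
the leading planted DEGs of the matching class, belong only to the spot's
pathways, and spot pathways are adjacent in collection order — so the
planted signal is a contiguous block under the canonical image ordering.
Background pathways draw members from non-DEG genes, keeping the
pathway-level planted signal exactly the two blocks.

Bulk cohorts give each sample a latent standardized burden z; signature
genes shift by 1.0·z, response odds follow a logistic in z, and survival is
exponential with log-hazard `hazard_log_ratio`·z (default −0.8; negative =
protective) with independent exponential censoring tuned to the requested
rate (default 20%).

What the generator does **not** emulate: discrete cell types and their
compositional shifts, gene–gene correlation beyond the planted structure,
batch effects, library-size variation beyond a scalar intercept, and
count-level noise (everything is Gaussian on the log scale). Passing tests
therefore certify the statistical machinery — recovery, calibration,
localization, reproducibility — under the planted model, not biological
performance on real cohorts.

### Problem sizes used in the checks

The default generator profile is deliberately reduced: 48 samples × 40
cells (1,920 cells) and 2,000 genes for the gene-level benchmark; 48 × 12
cells and a 12-pathway universe with 16 × 4 spots (scaled down from the
full 64 × 8) for the pathway stage, trained 10 epochs. Full-scale profiles
(16,290 cells, 186 pathways, 383 image rows, 64 × 8 spots, 30 epochs) are
reachable through the same configs.

## Numerical and design notes

* Seeds: a single global seed fans out to per-stage derived seeds
  (seed + stage index); every stochastic routine takes an explicit seed and
  uses a local `numpy` generator — no global RNG state.
* Zero-variance features standardize to 0; all-tied rank-sum tests return
  p = 1; all-censored survival input is a validation error for the log-rank
  test and a flat KM curve.
* Expression matrices validate non-negativity, finiteness and identifier
  uniqueness on construction; gene symbols are matched case-sensitively
  after whitespace stripping, with no alias resolution (alias mapping would
  silently change DEG sets).
* Clinical response labels CR/PR map to responder and PD/SD to
  non-responder at read time.
* The manifest contains no timestamps, so identical configs produce
  byte-identical manifests; network stages are included because the numpy
  core is deterministic.

## Limitations

* The 2-D CNN's receptive field and hence its attribution depend on the
  image ordering; the canonical ordering is recorded but alternatives are
  not explored automatically.
* Grad-CAM resolution is the final conv activation (half the image
  resolution minus the valid-conv margin); upsampling blurs spot borders,
  so extracted spots can span a superset of the planted genes.
* The FNN uses L2 rather than dropout regularization (see above).
* Only univariate Cox and a single (time, event) endpoint are supported;
  multivariate models, competing risks and endpoint semantics are out of
  scope.
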