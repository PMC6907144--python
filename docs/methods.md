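# Methods

## Model overview

`eigencell` treats cell-type assignment as supervised classification in a
data-driven orthogonal basis. The core assumption is that class identity
is encoded in many small, correlated shifts in gene expression rather than
in a handful of marker genes; linear combinations of genes (principal
components of the standardized log-CPM matrix) concentrate that spread
signal into a few coordinates, and components carrying no class signal can
be discarded before any classifier sees them. Classification then happens
entirely in the training coordinate system: test cells are standardized
with the training gene means/SDs and projected through the training
rotation, never re-decomposed, so a trained model is a fixed map from
counts to class probabilities.

The rejection option is integral to the method, not a post hoc filter: a
one-vs-all Platt-calibrated probability is produced per class, the
probabilities are deliberately *not* normalized across classes, and a cell
is labeled only when its best probability strictly exceeds the threshold.
A cell resembling none of the training classes therefore receives low
probabilities everywhere and stays "Unassigned".

## Pipeline stages and parameters

| stage | parameter | default | notes |
|---|---|---|---|
| cell QC | `n_mads` | 3 | window = median ± n_mads · 1.4826·MAD on library size, mito fraction, ribo fraction; a metric with MAD = 0 is skipped |
| gene filter | `min_cell_frac` | 0.01 | detection (count > 0) fraction |
| gene filter | `min_mean_cpm` | 5 | genes kept when mean CPM across cells is strictly above this |
| normalization | — | log2(CPM+1) | per-cell totals to 10⁶ |
| SVD | `n_components` | min(n−1, m, 100) | the variance filter usually reduces the informative set far below this |
| variance filter | `var_threshold` | 1e-4 | fraction of total ‖M‖²_F |
| PC selection | `alpha` | 0.05 | BH-adjusted two-tailed rank-sum p per PC, family = the variance-filtered set of one class's tests |
| SVM grid | σ | reciprocals of the {0.1, 0.5, 0.9} quantiles of pairwise squared distances | median-heuristic bracket |
| SVM grid | C | {0.25, 0.5, 1, 2, 4, 8, 16} | ties prefer smaller C, then smaller σ |
| CV | `folds` | 10 | stratified; reduced with a warning when the smaller class has fewer cells |
| rejection | `threshold` | 0.9 | strict comparison; exactly 0.9 → Unassigned |
| balancing | `balance` | none | "smote" interpolates minority neighbors before training |

QC is a single pass: summary statistics are computed once and outliers
removed once. Re-running QC on its own output recomputes the statistics
and may remove further cells; the test suite asserts only that repeated
application reaches a fixed point.

## Numerical choices

- **SVD backend.** Matrices whose smaller dimension is ≤ 1500 use a dense
  LAPACK SVD (deterministic by construction); larger problems use a seeded
  randomized solver. Either way the sign ambiguity is removed by forcing
  each rotation column's largest-magnitude loading positive, so results
  are reproducible across solvers.
- **Variance explained under truncation** divides by the exact squared
  Frobenius norm of M, not the truncated spectrum, so the 0.01% filter
  refers to total variance.
- **Zero-variance genes** are dropped before scaling (scaling is undefined
  for them) and recorded; test genes missing from the training scaling are
  imputed at the gene mean (scaled value 0), which is unbiased and
  preserves the rotation dimensions. Fewer than 50% of training genes
  present in a test matrix is an error, not a silent projection.
- **Rank-sum p-values** are exact (full enumeration) when both groups have
  ≤ 8 tie-free observations, else the normal approximation with tie and
  continuity corrections. Equal adjusted p-values rank by PC index.
- **Platt calibration** is fitted by damped Newton with backtracking on
  the regularized targets (N₊+1)/(N₊+2) and 1/(N₋+2), on *out-of-fold*
  decision values so the sigmoid never sees its own training fit; the fit
  agrees with scikit-learn's reference implementation to ~1e-5 and fails
  loudly after 100 iterations rather than returning a bad fit.
- **AUROC** is the midrank U-statistic (ties count 0.5), making a constant
  predictor exactly 0.5. **AUPRC** uses non-interpolated step-wise
  integration; a constant predictor therefore scores the class prevalence,
  the standard convention.
- **Ties at the maximum probability** resolve to the lexicographically
  smallest class name, keeping predictions deterministic.

## Evaluation conventions

Sensitivity and specificity are rejection-aware: an unassigned cell counts
as incorrect for its true class, so sensitivity = TP / (all true
positives, unassigned included). "Bootstrap" evaluation is repeated
stratified 75/25 splitting with percentile CIs — resampling of splits, not
resampling with replacement — because the quantity of interest is
generalization to held-out cells, and the seeded partitions can be shared
across competing methods. Read-depth robustness uses exact
without-replacement (multivariate hypergeometric) thinning so a
downsampled cell is a true subsample of its reads.

## What the simulator does and does not capture

`generate_class_counts` draws per-gene baseline means log-normally, gives
each class a disjoint set of effect genes shifted ±effect_size in log2
mean, and samples gamma-Poisson (negative binomial) counts at a per-cell
library size drawn uniformly from `library_size_range`. Defaults — 200
cells/class, 2000 genes, 200 effect genes, log2 effect 1.0, dispersion
0.5, libraries in [20k, 60k] — are the package's reference conditions: a
moderately deep droplet-style experiment where each class differs through
many modest shifts, which is exactly the regime the eigen-decomposition
approach targets. The generator also tags mitochondrial/ribosomal genes
(so QC has real inputs), can inject a class absent from training (to
exercise rejection), and can layer hierarchical effects (parent shifts
shared by all descendant classes, child shifts on disjoint genes).

It deliberately omits gene–gene correlation beyond the class structure,
zero inflation beyond what NB sampling produces, UMI saturation, and
realistic batch chemistry (an optional per-gene log-fold batch shift
exists only to measure degradation; no correction is implemented). Passing
tests therefore demonstrate that the pipeline recovers class structure of
the assumed form from noisy counts — not that it is robust to every
artifact of real platforms, and in particular not that cross-platform
prediction works without prior embedding alignment, which is outside this
package's scope.

## Design choices where the design was open

- The PC-selection test is the unpaired Mann-Whitney rank-sum test; the
  groups (class vs rest) are unpaired, so a signed-rank test would not
  apply. BH correction is applied within one class's family of tests, not
  pooled across classes.
- Model selection maximizes mean CV AUROC: threshold-free and aligned with
  the reported metrics.
- Binary problems train two one-vs-all models by default; an optional
  collapsed mode trains one model and uses the complement probability for
  the negative class. With two independent models the two probabilities
  need not be complementary, and the max rule applies unchanged.
- The differential-expression baseline screens genes by rank-sum BH < 0.05
  plus |mean log2 difference| > 1 and trains an SVM on the surviving
  genes' log-CPM values; it exists to quantify the advantage of PC
  features over gene features on the same data.
- Class minimum of 20 cells produces a warning, not an error (hard error
  below 2): accuracy degrades smoothly with class size and the cutoff is
  advisory.

## Problem sizes

The test suite and the acceptance script run on simulations of 60–200
cells per class and 300–2000 genes with 3–10-fold CV. These sizes were
chosen so that every experiment's outcome is far from its decision
boundary under the reference conditions while a complete run stays in the
seconds-to-minutes range on one core; the pipeline itself has no
small-data assumptions and scales to atlas-sized references limited only
by the SVD and the SVM kernel matrices.

## Known limitations

- No batch/platform integration: training cohorts from multiple chemistries
  must be aligned upstream; the package accepts pre-aligned matrices.
- One-vs-all probabilities are uncalibrated *jointly*: they do not sum to
  one, by design, so they should not be read as a posterior over classes.
- The SMOTE implementation interpolates in the informative-PC space, which
  is appropriate for the SVM features but does not produce synthetic
  *count* profiles.
- Hierarchical prediction is hard-gated: a cell misassigned at the root
  cannot be recovered by a child model.
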