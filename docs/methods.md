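# Methods

## Problem and model

Given a bulk RNA-seq expression vector x ∈ R^p, the goal is a prediction
interval Ĉ(x) = [lower, upper] for the sample's malignant cell fraction
y ∈ [0, 1] satisfying P{y ∈ Ĉ(x)} ≥ 1 − α for a user-chosen significance
level α, without distributional assumptions beyond exchangeability of
calibration and test samples. The pipeline combines (a) supervised training
data manufactured by pseudo-bulk simulation, (b) a two-headed
quantile-regression network, and (c) split conformal calibration.

The network estimates the conditional quantiles at levels α/2 and 1 − α/2.
The halved level is deliberate: the target is one coordinate of a two-class
composition (malignant vs normal), and the multivariate quantile-regression
convention splits the miscoverage budget across the two classes. Each
significance level gets its own trained model; the two heads of one model
share all trunk parameters.

## Pseudo-bulk simulation

For a subject's QC'd single-cell matrix, each artificial sample fixes a
total cell count N, draws the malignant count n_m uniformly from the
integers {0, …, N} (endpoints included — the label y = n_m/N must be an
exact rational), then draws n_m malignant and N − n_m normal cells. The
with-replacement rule is evaluated per class: a class is sampled with
replacement only when its pool is smaller than the request, otherwise
without. The bulk vector is the exact column sum of the selected cells, and
selection indices can be logged so conservation is checkable after the
fact. Cells of different subjects are never combined in one sample, which
preserves within-subject gene covariation and keeps cross-subject
heterogeneity visible to the evaluation. Defaults are N = 3000 cells per
sample and T = 200 samples per subject; the validation study scales these
down (see below).

## Preprocessing

- **Gene alignment and variance filter.** Only genes present in both the
  training and prediction matrices are kept (gene *identities* only — no
  statistic of the test data enters the fit), minus genes whose raw
  training-matrix variance falls below 0.1. The population (1/n) variance
  of the raw, pre-transform matrix is used, and the training-matrix gene
  order is kept so fitted specs are portable.
- **TF-IDF.** out_ij = (X_ij / Σ_j X_ij) · log(T / (Σ_i X_ij + 1)), with T
  the number of rows of the matrix being transformed. The formula is applied
  verbatim: the IDF may be negative (gene total > T − 1), and it is
  recomputed on each matrix rather than frozen from training — the same
  workflow is applied to every dataset, which is what makes the model
  transferable across cohorts and platforms. Rows must have positive sums;
  an all-zero gene is fine (IDF = log T).
- **Row MinMax.** Each sample row is rescaled to [0, 1] by its own min/max;
  a constant row maps to zeros by convention. The subsequent network never
  sees raw scales, which absorbs library-size and platform differences.
- **Perturbation model.** For robustness experiments, noise
  max(0, X_ij + N(0, λ·X_ij)) is applied to raw expression before the
  transform; λ is read as the noise *variance* per unit expression, not the
  standard deviation. Zero entries are fixed points.

## Quantile network

Four fully connected hidden layers (defaults 512-256-128-64) with ReLU and
inverted dropout (rate 0.2) after each, and a two-unit linear head. Training
minimises the summed pinball losses of the two heads with Adam
(lr 1e-4, batch 128, 100 epochs by default); dropout is the only
regulariser. The head is linear and unbounded — clipping to [0, 1] happens
at conformalisation, where it cannot reduce coverage of a value in [0, 1].
If a row's raw outputs cross, they are swapped (the minimal monotonicity
repair). The network is implemented directly on numpy (explicit
forward/backward passes and Adam); at these layer widths that is both fast
and exactly reproducible from a seed, with no framework dependency. Weight
init is He-normal, seeded; minibatch order, dropout masks and the 7:3 split
all derive deterministically from one experiment seed via spawned seed
sequences. A non-finite loss raises a divergence error rather than
continuing silently.

## Conformal calibration

The pooled simulated data is split 7:3 into proper training and calibration
parts (a larger training share improves the quantile fits; the calibration
part only needs enough points for a stable order statistic). Conformity
scores E_i = max(q̂_lo(X_i) − y_i, y_i − q̂_hi(X_i)) are negative inside the
interval and positive outside; the adjustment is the k-th smallest score
with k = ⌈(1 − α/2)(n + 1)⌉, capped at the maximum when k > n — the standard
finite-sample-corrected empirical quantile, with no interpolation. Widening
both bounds by the adjustment restores the marginal coverage guarantee.
Intervals are clipped to [0, 1] by default (fractions are proportions);
clipping can be disabled.

## Synthetic single-cell generator

The generator stands in for a real labeled scRNA-seq reference. Counts are
negative binomial via a gamma–Poisson mixture (dispersion 2.0), per-gene
base means log-normal (σ = 1) around base_mean = 1, giving realistic
sparsity (~40–50% zeros at the default depth). A fraction (default 20%) of
genes is differentially expressed between classes with fold change
2^log2_effect (default 4×), half up in each class. In a cohort, gene-level
parameters are drawn once from a master seed and shared by all subjects;
each subject adds a mild lognormal random effect (σ = 0.1) on gene means and
its own sampling noise. Subjects are therefore exchangeable draws from one
population with cross-subject heterogeneity — the regime in which the
conformal guarantee transfers to a held-out subject. What the generator does
*not* emulate: batch/platform effects, ambient RNA, doublets, cell-type
substructure beyond two classes, and gene–gene correlation beyond the
class/subject means. Passing tests therefore demonstrate the machinery and
its guarantees under exchangeability, not performance on real cross-platform
data.

QC defaults follow the common droplet workflow: cells with < 500 detected
genes and genes detected in < 5 cells are dropped (thresholds scale with the
panel: the 500-gene validation study uses min_genes = 50), then per-cell
totals are equalised; the normalisation target defaults to the median
per-cell total. Order: cells, then genes, then normalisation. Supplementary
outlier-removal steps that cannot be specified from first principles are out
of scope.

## Evaluation protocol

Leave-one-subject-out: hold out one subject's dataset, pool the rest, fit
the transform spec on the pool (intersecting gene ids with the held-out
set), transform, split 7:3, train, calibrate, predict the held-out subject.
Coverage and average interval length are reported per fold. The unified
model pools all subjects instead, for prediction on external bulk data.
The robustness experiment perturbs only the held-out expression (models and
calibration untouched) at λ ∈ {0.01, 0.05, 0.1} plus a λ = 0 control.
Ablations: `use_calibration=False` trains on the whole pool and reports raw
network quantiles; `apply_tfidf=False` feeds MinMax-only features.

## Validation study sizes and expectations

The bundled study (`conformix.protocols`, also run by
`scripts/acceptance.py`) uses 4 subjects × 2,000 cells × 500 genes, 300
pseudo-bulk samples per subject at N = 300, a 64-32-16-8 network trained 40
epochs at lr 1e-4, and three seeds — about a minute on one CPU. At this
scale the briefly trained network underfits and the conformal adjustment
does most of the work: coverage lands at or above nominal (≈97% at α = 0.05,
miscoverage ≈5% at α = 0.10) but intervals are wide (L_avg ≈ 0.9). With the
default architecture, more epochs and paper-scale data (tens of thousands of
training mixtures) the same code yields tighter intervals; the study sizes
were chosen so the full pipeline, including three seeds, runs comfortably on
a laptop.

## Known limitations

- Two cell classes only; no multivariate prediction regions.
- Coverage is marginal, not conditional: under-coverage can concentrate in
  parts of the fraction range even when the average is nominal.
- The guarantee needs exchangeability; strong batch effects between the
  reference-derived mixtures and real bulk data can break it, and TF-IDF +
  MinMax mitigate but do not remove such shifts.
- IDF recomputed per dataset means single-sample prediction matrices get a
  degenerate IDF (T = 1); predict batches, or reuse a training-fitted
  transform when T is very small.
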