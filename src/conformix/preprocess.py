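"""Expression preprocessing for the quantile network.

The pipeline is: (1) restrict to genes present in both the training and the
prediction matrices and drop genes whose raw training-set variance falls
below a threshold; (2) a TF-IDF reweighting that treats genes as terms and
bulk samples as documents,

    TF(X_ij)  = X_ij / sum_j X_ij
    IDF(G_j)  = log( T / (sum_i X_ij + 1) )
    out_ij    = TF(X_ij) * IDF(G_j),

with T the number of samples of the matrix being transformed -- lowly
expressed genes receive larger weights, counteracting the orders-of-magnitude
imbalance of expression levels; and (3) a per-sample MinMax rescaling of each
row to [0, 1]. A multiplicative-noise perturbation model is provided for
robustness experiments: Gaussian noise with variance proportional to the
expression level, clamped at zero.

The IDF is deliberately applied verbatim: it may be negative when a gene's
total exceeds T - 1, and it is recomputed on whichever matrix is being
transformed rather than frozen from training (the same workflow is applied
to every dataset). The variance filter uses the population (1/n) variance of
the raw, pre-TF-IDF training matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bulk import BulkDataset


@dataclass
class TransformSpec:
    """The gene set and transform switches fitted on a training matrix."""

    retained_genes: np.ndarray
    variance_threshold: float = 0.1
    apply_tfidf: bool = True

    def __post_init__(self) -> None:
        self.retained_genes = np.asarray(self.retained_genes, dtype=object)

    @property
    def n_genes(self) -> int:
        return len(self.retained_genes)


def align_and_filter_genes(train: BulkDataset, test: BulkDataset | None = None,
                           variance_threshold: float = 0.1,
                           apply_tfidf: bool = True) -> TransformSpec:
    """Fit a :class:`TransformSpec`: shared genes, in training order, whose
    raw training variance is >= ``variance_threshold``.

    Only gene *identities* of ``test`` are used (no test statistics leak into
    the spec). ``test=None`` skips the intersection step.
    """
    if test is None:
        shared = set(train.gene_ids)
    else:
        shared = set(train.gene_ids) & set(test.gene_ids)
    if not shared:
        raise ValueError("training and test datasets share no genes")
    keep = []
    var = train.expression.var(axis=0)  # population variance, raw counts
    for j, g in enumerate(train.gene_ids):
        if g in shared and var[j] >= variance_threshold:
            keep.append(g)
    if not keep:
        raise ValueError("variance filter removed every shared gene")
    return TransformSpec(retained_genes=np.asarray(keep, dtype=object),
                         variance_threshold=variance_threshold,
                         apply_tfidf=apply_tfidf)


def tfidf(X: np.ndarray) -> np.ndarray:
    """TF-IDF reweighting of a samples x genes matrix.

    Every row must have a positive sum. A gene with zero total is allowed
    (its IDF is log T). The IDF uses the matrix being transformed, so the
    same function serves training and prediction data alike.
    """
    X = np.asarray(X, dtype=float)
    T = X.shape[0]
    row_sums = X.sum(axis=1, keepdims=True)
    if (row_sums <= 0).any():
        raise ValueError("tfidf requires every sample (row) to have a positive sum")
    tf = X / row_sums
    idf = np.log(T / (X.sum(axis=0) + 1.0))
    return tf * idf


def minmax_rows(X: np.ndarray) -> np.ndarray:
    """Rescale each row to [0, 1] by its own min and max.

    Constant rows (max == min) map to all zeros.
    """
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(X)
    nz = (span > 0).ravel()
    out[nz] = (X[nz] - lo[nz]) / span[nz]
    return out


def apply_transform(data: BulkDataset, spec: TransformSpec) -> np.ndarray:
    """Subset to the spec's genes, then TF-IDF (unless ablated) and row
    MinMax. Returns the feature matrix the network consumes."""
    sub = data.subset_genes(spec.retained_genes)
    X = sub.expression
    if spec.apply_tfidf:
        X = tfidf(X)
    return minmax_rows(X)


def perturb(X: np.ndarray, lam: float,
            rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Add zero-mean Gaussian noise with variance ``lam * X_ij`` to every
    entry, clamping negatives to zero. ``lam=0`` returns X unchanged; zero
    entries stay zero (their noise variance is zero)."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    X = np.asarray(X, dtype=float)
    if lam == 0:
        return X.copy()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    noise = rng.normal(loc=0.0, scale=np.sqrt(lam * X))
    return np.maximum(0.0, X + noise)


def perturb_dataset(data: BulkDataset, lam: float,
                    rng: np.random.Generator | int | None = None) -> BulkDataset:
    """Return a copy of ``data`` with perturbed expression."""
    return BulkDataset(
        expression=perturb(data.expression, lam, rng),
        fractions=None if data.fractions is None else data.fractions.copy(),
        subject_id=data.subject_id,
        gene_ids=data.gene_ids.copy(),
        cells_per_sample=data.cells_per_sample,
    )
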