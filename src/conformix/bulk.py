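"""Pseudo-bulk simulation: artificial bulk RNA-seq samples with known
malignant fractions, built by summing sampled single cells.

For each artificial sample a total cell count N is fixed, the malignant cell
number n_m is drawn uniformly from the integers {0, ..., N}, and n_m
malignant plus N - n_m normal cells are drawn from a single subject's
reference -- with replacement when the requested number exceeds that class's
pool, without replacement otherwise. The sample's expression vector is the
gene-wise sum of the selected cells and its label is the exact fraction
n_m / N. Cells from different subjects are never mixed within one sample, so
each simulated dataset carries one subject's expression idiosyncrasies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import SingleCellMatrix


@dataclass
class BulkDataset:
    """Sample x gene expression with (optionally) known malignant fractions."""

    expression: np.ndarray
    fractions: np.ndarray | None
    subject_id: str
    gene_ids: np.ndarray
    cells_per_sample: int | None = None
    selection_log: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.expression.ndim != 2:
            raise ValueError("expression must be 2-D (samples x genes)")
        if (self.expression < 0).any():
            raise ValueError("expression must be non-negative")
        if self.expression.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids must match the expression columns")
        if self.fractions is not None:
            self.fractions = np.asarray(self.fractions, dtype=float)
            if len(self.fractions) != self.expression.shape[0]:
                raise ValueError("fractions length must equal the number of samples")
            if ((self.fractions < 0) | (self.fractions > 1)).any():
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def subset_genes(self, gene_ids) -> "BulkDataset":
        """Return a copy restricted to ``gene_ids``, in that order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        try:
            cols = [index[g] for g in gene_ids]
        except KeyError as err:
            raise KeyError(f"gene {err.args[0]!r} absent from dataset") from None
        return BulkDataset(
            expression=self.expression[:, cols],
            fractions=None if self.fractions is None else self.fractions.copy(),
            subject_id=self.subject_id,
            gene_ids=np.asarray(list(gene_ids), dtype=object),
            cells_per_sample=self.cells_per_sample,
        )


def concat_bulk(datasets: list[BulkDataset]) -> BulkDataset:
    """Stack datasets that share an identical gene order."""
    if not datasets:
        raise ValueError("no datasets to concatenate")
    ref = datasets[0].gene_ids
    for d in datasets[1:]:
        if len(d.gene_ids) != len(ref) or (d.gene_ids != ref).any():
            raise ValueError("datasets must share an identical gene order; align genes first")
    fracs = None
    if all(d.fractions is not None for d in datasets):
        fracs = np.concatenate([d.fractions for d in datasets])
    return BulkDataset(
        expression=np.vstack([d.expression for d in datasets]),
        fractions=fracs,
        subject_id="pooled",
        gene_ids=ref.copy(),
        cells_per_sample=datasets[0].cells_per_sample,
    )


def _draw_class(pool: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw k cell indices from a class pool: with replacement only when the
    pool is smaller than the request."""
    if k == 0:
        return np.empty(0, dtype=int)
    if len(pool) == 0:
        raise ValueError("required cell class is empty in this subject")
    replace = len(pool) < k
    return rng.choice(pool, size=k, replace=replace)


def simulate_bulk_sample(sc_mat: SingleCellMatrix, N: int, n_m: int,
                         rng: np.random.Generator,
                         return_indices: bool = False):
    """Simulate one pseudo-bulk sample with exactly ``n_m`` malignant cells.

    Returns ``(expression_vector, fraction)`` where the expression vector is
    the gene-wise sum over the N selected cells and the fraction is exactly
    ``n_m / N``. With ``return_indices=True`` the selected row indices are
    returned as a third element (for provenance / conservation checks).
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 <= n_m <= N:
        raise ValueError(f"n_m must lie in [0, N]; got {n_m} with N={N}")
    labels = sc_mat.cell_class
    mal_pool = np.flatnonzero(labels == "malignant")
    norm_pool = np.flatnonzero(labels == "normal")
    idx = np.concatenate([
        _draw_class(mal_pool, n_m, rng),
        _draw_class(norm_pool, N - n_m, rng),
    ])
    expr = sc_mat.counts[idx].sum(axis=0)
    frac = n_m / N
    if return_indices:
        return expr, frac, idx
    return expr, frac


def simulate_bulk_dataset(sc_mat: SingleCellMatrix, N: int = 3000, T: int = 200,
                          rng: np.random.Generator | int | None = None,
                          log_indices: bool = False) -> BulkDataset:
    """Simulate ``T`` pseudo-bulk samples from one subject.

    Each sample's malignant count n_m is uniform on the integers
    {0, 1, ..., N} (endpoints included), so the fraction labels are exact
    multiples of 1/N spanning [0, 1].
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    expr = np.empty((T, sc_mat.n_genes))
    fracs = np.empty(T)
    log: list | None = [] if log_indices else None
    for t in range(T):
        n_m = int(rng.integers(0, N + 1))  # inclusive upper bound
        if log_indices:
            expr[t], fracs[t], idx = simulate_bulk_sample(sc_mat, N, n_m, rng, return_indices=True)
            log.append(idx)
        else:
            expr[t], fracs[t] = simulate_bulk_sample(sc_mat, N, n_m, rng)
    return BulkDataset(expression=expr, fractions=fracs, subject_id=sc_mat.subject_id,
                       gene_ids=sc_mat.gene_ids.copy(), cells_per_sample=N,
                       selection_log=log)
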