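"""Synthetic labeled single-cell data and single-cell quality control.

The simulator emulates the structure a droplet scRNA-seq reference provides
for pseudo-bulk deconvolution: per-subject cell-by-gene count matrices with
two cell classes (malignant / normal), a subset of differentially expressed
genes separating the classes, and overdispersed counts. Counts follow a
negative binomial generated as a gamma--Poisson mixture, with per-gene base
means drawn log-normally -- the simplest model that yields realistic sparsity
and mean-variance behaviour.

Quality control mirrors the standard Scanpy workflow: drop cells with too few
detected genes, drop genes detected in too few cells, then rescale each cell
to a common total count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import scanpy as sc


class EmptyDatasetError(ValueError):
    """Raised when a QC filter would remove every cell or gene."""


@dataclass
class SingleCellMatrix:
    """A labeled cell x gene count matrix for a single subject.

    Attributes
    ----------
    counts
        Dense array of shape (n_cells, n_genes), non-negative. Raw integer
        counts from the simulator; real-valued after ``normalize_total``.
    cell_class
        Array of ``"malignant"`` / ``"normal"`` labels, one per cell.
    subject_id
        Identifier of the donor the cells came from.
    gene_ids
        Unique gene identifiers, one per column.
    """

    counts: np.ndarray
    cell_class: np.ndarray
    subject_id: str
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.cell_class = np.asarray(self.cell_class, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_class) != n_cells:
            raise ValueError("cell_class length must equal the number of cells")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length must equal the number of genes")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        bad = set(self.cell_class) - {"malignant", "normal"}
        if bad:
            raise ValueError(f"unknown cell classes: {sorted(bad)}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(X=self.counts.copy())
        adata.obs["cell_class"] = list(self.cell_class)
        adata.obs["subject_id"] = self.subject_id
        adata.var_names = [str(g) for g in self.gene_ids]
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, subject_id: str | None = None) -> "SingleCellMatrix":
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = np.asarray(X.todense())
        if subject_id is None:
            subject_id = str(adata.obs["subject_id"].iloc[0]) if "subject_id" in adata.obs else "unknown"
        return cls(
            counts=np.asarray(X, dtype=float),
            cell_class=adata.obs["cell_class"].to_numpy(),
            subject_id=subject_id,
            gene_ids=adata.var_names.to_numpy(),
        )


@dataclass
class SyntheticScConfig:
    """Parameters of the two-class negative-binomial count simulator.

    ``de_gene_frac`` of the genes are differentially expressed between the
    classes with a mean ratio of ``2**log2_effect`` (up in malignant cells for
    half of them, up in normal cells for the other half). ``dispersion`` is
    the negative-binomial size parameter (smaller = more overdispersed).
    """

    n_cells: int = 2000
    n_genes: int = 500
    malignant_prop: float = 0.5
    de_gene_frac: float = 0.2
    log2_effect: float = 2.0
    dispersion: float = 2.0
    base_mean: float = 1.0
    seed: int = 0
    subject_id: str = "S0"
    subject_sigma: float = 0.1

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        if not 0.0 < self.malignant_prop < 1.0:
            raise ValueError("malignant_prop must lie in (0, 1)")
        if not 0.0 <= self.de_gene_frac <= 1.0:
            raise ValueError("de_gene_frac must lie in [0, 1]")
        if self.log2_effect <= 0:
            raise ValueError("log2_effect must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        if self.subject_sigma < 0:
            raise ValueError("subject_sigma must be non-negative")


@dataclass
class GeneParams:
    """Gene-level parameters shared by every subject of a cohort.

    ``mean_malignant`` / ``mean_normal`` are per-gene expected counts per
    class before the subject-level random effect.
    """

    mean_malignant: np.ndarray
    mean_normal: np.ndarray
    de_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def draw_gene_params(config: SyntheticScConfig, rng: np.random.Generator) -> GeneParams:
    """Draw per-gene class means: log-normal base means, DE genes shifted
    by ``log2_effect`` (half up in the malignant class, half down)."""
    G = config.n_genes
    base = config.base_mean * rng.lognormal(mean=0.0, sigma=1.0, size=G)
    n_de = int(round(config.de_gene_frac * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    de_mask = np.zeros(G, dtype=bool)
    de_mask[de_idx] = True
    fold = 2.0 ** config.log2_effect
    mean_mal = base.copy()
    mean_norm = base.copy()
    up_in_malignant = de_idx[: n_de // 2]
    up_in_normal = de_idx[n_de // 2:]
    mean_mal[up_in_malignant] *= fold
    mean_norm[up_in_normal] *= fold
    return GeneParams(mean_malignant=mean_mal, mean_normal=mean_norm, de_mask=de_mask)


def _nb_counts(mean: np.ndarray, dispersion: float, size: tuple[int, int],
               rng: np.random.Generator) -> np.ndarray:
    # gamma-Poisson mixture: lambda ~ Gamma(r, mean/r), counts ~ Poisson(lambda)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=size)
    return rng.poisson(lam).astype(float)


def generate_subject_sc(config: SyntheticScConfig,
                        gene_params: GeneParams | None = None) -> SingleCellMatrix:
    """Simulate one subject's labeled single-cell count matrix.

    Exactly ``round(n_cells * malignant_prop)`` cells are malignant. When
    ``gene_params`` is omitted they are drawn from ``config.seed``, so two
    calls with the same config are bit-identical; pass shared ``gene_params``
    to make several subjects draws from a common population (see
    :func:`generate_cohort`).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if gene_params is None:
        gene_params = draw_gene_params(config, rng)
    # subject-level random effect: a mild lognormal wobble on every gene mean
    if config.subject_sigma > 0:
        effect = rng.lognormal(mean=0.0, sigma=config.subject_sigma, size=config.n_genes)
    else:
        effect = np.ones(config.n_genes)
    n_mal = int(round(config.n_cells * config.malignant_prop))
    n_norm = config.n_cells - n_mal
    mal = _nb_counts(gene_params.mean_malignant * effect, config.dispersion,
                     (n_mal, config.n_genes), rng)
    norm = _nb_counts(gene_params.mean_normal * effect, config.dispersion,
                      (n_norm, config.n_genes), rng)
    counts = np.vstack([mal, norm])
    labels = np.array(["malignant"] * n_mal + ["normal"] * n_norm, dtype=object)
    # shuffle so class labels are not block-ordered
    order = rng.permutation(config.n_cells)
    gene_ids = np.array([f"gene_{j}" for j in range(config.n_genes)], dtype=object)
    return SingleCellMatrix(counts=counts[order], cell_class=labels[order],
                            subject_id=config.subject_id, gene_ids=gene_ids)


def generate_cohort(config: SyntheticScConfig, n_subjects: int,
                    seed: int | None = None) -> list[SingleCellMatrix]:
    """Simulate a cohort of subjects drawn from one gene-level population.

    Gene base means and the DE gene set are drawn once from the master seed;
    each subject then gets its own sampling seed plus a mild subject-level
    random effect, so subjects are exchangeable draws from a common
    population with cross-subject heterogeneity.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(master)
    gene_params = draw_gene_params(config, rng)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    cohort = []
    for i in range(n_subjects):
        sub_cfg = replace(config, seed=int(subject_seeds[i]), subject_id=f"S{i}")
        cohort.append(generate_subject_sc(sub_cfg, gene_params=gene_params))
    return cohort


def _apply_scanpy_filter(sc_mat: SingleCellMatrix, fn, what: str, **kwargs) -> SingleCellMatrix:
    adata = sc_mat.to_anndata()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fn(adata, **kwargs)
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise EmptyDatasetError(f"QC removed every {what}")
    return SingleCellMatrix.from_anndata(adata, subject_id=sc_mat.subject_id)


def filter_cells(sc_mat: SingleCellMatrix, min_genes: int = 500) -> SingleCellMatrix:
    """Drop cells with fewer than ``min_genes`` detected (count > 0) genes."""
    if min_genes <= 0:
        return sc_mat
    return _apply_scanpy_filter(sc_mat, sc.pp.filter_cells, "cell", min_genes=min_genes)


def filter_genes(sc_mat: SingleCellMatrix, min_cells: int = 5) -> SingleCellMatrix:
    """Drop genes detected (count > 0) in fewer than ``min_cells`` cells."""
    if min_cells <= 0:
        return sc_mat
    return _apply_scanpy_filter(sc_mat, sc.pp.filter_genes, "gene", min_cells=min_cells)


def normalize_total(sc_mat: SingleCellMatrix, target_sum: float | None = None) -> SingleCellMatrix:
    """Rescale every cell to the same total count.

    ``target_sum=None`` uses the median of the per-cell totals, the common
    convention. Cells with zero total are an error: run :func:`filter_cells`
    first.
    """
    totals = sc_mat.counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError(
            "normalize_total found cells with zero total count; run filter_cells first"
        )
    adata = sc_mat.to_anndata()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.normalize_total(adata, target_sum=target_sum)
    return SingleCellMatrix.from_anndata(adata, subject_id=sc_mat.subject_id)


def qc_pipeline(sc_mat: SingleCellMatrix, min_genes: int = 500, min_cells: int = 5,
                target_sum: float | None = None) -> SingleCellMatrix:
    """Filter cells, then genes, then normalize totals (the standard order)."""
    out = filter_cells(sc_mat, min_genes=min_genes)
    out = filter_genes(out, min_cells=min_cells)
    return normalize_total(out, target_sum=target_sum)
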