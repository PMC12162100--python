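"""End-to-end synthetic validation protocol.

A self-contained study that exercises the whole pipeline on data with a
known ground truth: simulate a cohort of subjects from one gene-level
population, run the single-cell QC, build per-subject pseudo-bulk datasets,
and evaluate leave-one-subject-out coverage and interval length of the
conformalized quantile network at one or more significance levels.

Default problem sizes are desk-scale: 4 subjects of 2,000 cells x 500
genes, 300 pseudo-bulk samples per subject at N = 300 cells each, and a
narrow network (hidden layers 64-32-16-8, 40 epochs). The QC thresholds are
scaled to the 500-gene panel (cells must detect >= 50 genes; genes must be
seen in >= 5 cells).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bulk import BulkDataset, simulate_bulk_dataset
from .evaluation import loo_cv
from .quantile_net import QuantileModelConfig
from .synthetic import SyntheticScConfig, generate_cohort, qc_pipeline


def default_study_config(alpha: float = 0.1, seed: int = 0) -> QuantileModelConfig:
    """The narrow network used by the synthetic validation study."""
    return QuantileModelConfig(hidden_sizes=(64, 32, 16, 8), dropout_rate=0.2,
                               learning_rate=1e-4, batch_size=128, epochs=40,
                               alpha=alpha, seed=seed)


def build_synthetic_cohort_bulk(seed: int, n_subjects: int = 4,
                                n_cells: int = 2000, n_genes: int = 500,
                                N: int = 300, T: int = 300,
                                min_genes: int = 50,
                                min_cells: int = 5) -> list[BulkDataset]:
    """Simulate the study cohort: QC'd single-cell subjects and their
    pseudo-bulk datasets, all driven by one seed."""
    sc_cfg = SyntheticScConfig(n_cells=n_cells, n_genes=n_genes, seed=int(seed))
    cohort = generate_cohort(sc_cfg, n_subjects, seed=int(seed))
    rng = np.random.default_rng(int(seed) + 10_000)
    datasets = []
    for sc_mat in cohort:
        sc_mat = qc_pipeline(sc_mat, min_genes=min_genes, min_cells=min_cells)
        datasets.append(simulate_bulk_dataset(sc_mat, N=N, T=T, rng=rng))
    return datasets


def coverage_study(alphas=(0.05, 0.10), seeds=(1, 2, 3),
                   **cohort_kwargs) -> pd.DataFrame:
    """Leave-one-out coverage / length at each significance level.

    One cohort is simulated per seed and reused across the alpha levels
    (each level trains its own models). Returns a tidy table with columns
    seed, alpha, fold, coverage, avg_length, miscoverage.
    """
    rows = []
    for seed in seeds:
        datasets = build_synthetic_cohort_bulk(seed, **cohort_kwargs)
        for alpha in alphas:
            config = default_study_config(alpha=alpha, seed=int(seed))
            reports = loo_cv(datasets, alpha, config, seed=int(seed))
            for rep in reports:
                rows.append({"seed": int(seed), "alpha": float(alpha),
                             "fold": rep.dataset_id,
                             "coverage": rep.coverage,
                             "avg_length": rep.avg_length,
                             "miscoverage": 1.0 - rep.coverage})
    return pd.DataFrame(rows)


def summarize_coverage(table: pd.DataFrame) -> pd.DataFrame:
    """Mean coverage / length / miscoverage per alpha, over folds and seeds."""
    return (table.groupby("alpha")[["coverage", "avg_length", "miscoverage"]]
            .mean().reset_index())
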