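"""Plain-text readers and writers for single-cell and bulk matrices.

Two single-cell layouts are supported: a dense CSV/TSV with one row per
cell, a ``cell_class`` column and one column per gene, and the sparse
MTX triple (matrix in MatrixMarket coordinate format, cells x genes, plus a
features file of gene ids and a labels file of per-cell classes). Bulk
matrices are dense CSV/TSV with one row per sample, one column per gene and
an optional ``fraction`` column holding the known malignant fraction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .bulk import BulkDataset
from .evaluation import IntervalReport
from .synthetic import SingleCellMatrix

_LABEL_COL = "cell_class"
_FRACTION_COL = "fraction"


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tsv.gz", ".txt")) else ","


def write_sc_dense(sc_mat: SingleCellMatrix, path) -> None:
    df = pd.DataFrame(sc_mat.counts, columns=[str(g) for g in sc_mat.gene_ids])
    df.insert(0, _LABEL_COL, list(sc_mat.cell_class))
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_sc_dense(path, subject_id: str | None = None) -> SingleCellMatrix:
    df = pd.read_csv(path, sep=_sep_for(path))
    if _LABEL_COL not in df.columns:
        raise ValueError(f"dense single-cell file must have a '{_LABEL_COL}' column")
    labels = df[_LABEL_COL].to_numpy(dtype=object)
    genes = [c for c in df.columns if c != _LABEL_COL]
    return SingleCellMatrix(
        counts=df[genes].to_numpy(dtype=float),
        cell_class=labels,
        subject_id=subject_id or Path(path).stem,
        gene_ids=np.asarray(genes, dtype=object),
    )


def read_sc_mtx(matrix_path, features_path, labels_path,
                subject_id: str | None = None) -> SingleCellMatrix:
    """Read a cells x genes MatrixMarket triple.

    ``features_path``: one gene id per line (first TSV column used).
    ``labels_path``: one cell class per line, or a TSV with a ``cell_class``
    column.
    """
    X = np.asarray(mmread(matrix_path).todense(), dtype=float)
    feats = pd.read_csv(features_path, sep="\t", header=None)
    genes = feats.iloc[:, 0].astype(str).to_numpy(dtype=object)
    lab_df = pd.read_csv(labels_path, sep="\t")
    if _LABEL_COL in lab_df.columns:
        labels = lab_df[_LABEL_COL].to_numpy(dtype=object)
    else:
        lab_df = pd.read_csv(labels_path, sep="\t", header=None)
        labels = lab_df.iloc[:, -1].astype(str).to_numpy(dtype=object)
    return SingleCellMatrix(counts=X, cell_class=labels,
                            subject_id=subject_id or Path(str(matrix_path)).stem,
                            gene_ids=genes)


def write_bulk(data: BulkDataset, path) -> None:
    df = pd.DataFrame(data.expression, columns=[str(g) for g in data.gene_ids])
    if data.fractions is not None:
        df[_FRACTION_COL] = data.fractions
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_bulk(path, subject_id: str | None = None) -> BulkDataset:
    df = pd.read_csv(path, sep=_sep_for(path))
    fracs = None
    if _FRACTION_COL in df.columns:
        fracs = df[_FRACTION_COL].to_numpy(dtype=float)
        df = df.drop(columns=[_FRACTION_COL])
    return BulkDataset(
        expression=df.to_numpy(dtype=float),
        fractions=fracs,
        subject_id=subject_id or Path(path).stem,
        gene_ids=df.columns.to_numpy(dtype=object),
    )


def write_report(report: IntervalReport, path) -> None:
    """Interval table as TSV: sample_id, lower, upper (+ y_true / covered
    when known), with alpha recorded in a column."""
    table = report.per_sample.copy()
    table["alpha"] = report.alpha
    table.to_csv(path, sep="\t", index=False)
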