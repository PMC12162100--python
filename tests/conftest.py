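import numpy as np
import pytest

from conformix import SingleCellMatrix, SyntheticScConfig, generate_subject_sc


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_sc():
    """A small simulated subject: 300 cells x 80 genes, 30% malignant."""
    cfg = SyntheticScConfig(n_cells=300, n_genes=80, malignant_prop=0.3,
                            seed=42, subject_id="S_test")
    return generate_subject_sc(cfg)


@pytest.fixture
def tiny_sc():
    """A hand-sized matrix with explicit counts for exact-arithmetic checks."""
    counts = np.array([
        [5, 0, 2, 0],
        [1, 1, 1, 1],
        [0, 3, 0, 4],
        [2, 2, 0, 0],
        [0, 0, 6, 1],
        [3, 0, 0, 2],
    ], dtype=float)
    labels = np.array(["malignant", "malignant", "malignant",
                       "normal", "normal", "normal"], dtype=object)
    genes = np.array(["gA", "gB", "gC", "gD"], dtype=object)
    return SingleCellMatrix(counts=counts, cell_class=labels,
                            subject_id="tiny", gene_ids=genes)
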