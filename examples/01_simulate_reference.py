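"""Simulate a labeled single-cell reference and run quality control.

Builds one subject's cell x gene count matrix with two cell classes
(malignant / normal), 20% differentially expressed genes and overdispersed
negative-binomial counts, then applies the standard QC: drop shallow cells,
drop rarely detected genes, equalize per-cell totals.
"""

import numpy as np

from conformix import SyntheticScConfig, generate_subject_sc, qc_pipeline

cfg = SyntheticScConfig(n_cells=2000, n_genes=500, malignant_prop=0.4,
                        de_gene_frac=0.2, log2_effect=2.0, seed=1,
                        subject_id="demo")
sc_mat = generate_subject_sc(cfg)
print(f"raw: {sc_mat.n_cells} cells x {sc_mat.n_genes} genes, "
      f"{(sc_mat.cell_class == 'malignant').sum()} malignant, "
      f"sparsity {np.mean(sc_mat.counts == 0):.2f}")

qc = qc_pipeline(sc_mat, min_genes=50, min_cells=5)
totals = qc.counts.sum(axis=1)
print(f"after QC: {qc.n_cells} cells x {qc.n_genes} genes, "
      f"per-cell total = {totals[0]:.1f} (uniform: {np.allclose(totals, totals[0])})")
# The uniform per-cell total removes library-size differences so that a
# pseudo-bulk mixture's composition, not its sequencing depth, drives the
# expression signal.
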