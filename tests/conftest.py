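import numpy as np
import pandas as pd
import pytest

from trapdiff import ExpressionMatrix


def make_matrix(values: np.ndarray, gene_ids=None, sample_meta=None,
                biotypes=None, chroms=None) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from raw pieces with sensible defaults."""
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    if sample_meta is None:
        # alternate INPUT/IP, sham/SNI so selectors have something to find
        rows = []
        for j in range(n_samples):
            rows.append({
                "sample_id": f"s{j}",
                "fraction": "INPUT" if j < n_samples // 2 else "IP",
                "condition": "sham" if j % 2 == 0 else "SNI",
                "cell_type": "GAD2", "timepoint": "D60", "replicate": j + 1,
            })
        sample_meta = pd.DataFrame(rows).set_index("sample_id")
    ann = pd.DataFrame({
        "gene_id": gene_ids,
        "biotype": biotypes or ["protein_coding"] * n_genes,
        "chromosome": chroms or ["chr1"] * n_genes,
    }).set_index("gene_id")
    frame = pd.DataFrame(values, index=gene_ids, columns=sample_meta.index)
    return ExpressionMatrix(frame, sample_meta, ann)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    return make_matrix(rng.lognormal(1.0, 1.5, size=(30, 6)))
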