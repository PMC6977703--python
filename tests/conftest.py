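import numpy as np
import pytest

from cerna_profiler.core_io import ExpressionMatrix

CONDITIONS = ["Sham", "PD", "NLID", "LID"]


def make_matrix(values, conditions=CONDITIONS, n_rep=2, gene_ids=None):
    """Matrix helper: ``values`` is genes x (conditions * n_rep)."""
    values = np.asarray(values, dtype=float)
    sample_ids = [f"{c}_r{r + 1}" for c in conditions for r in range(n_rep)]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        gene_ids=list(gene_ids),
        sample_ids=sample_ids,
        condition_of_sample={s: s.rsplit("_r", 1)[0] for s in sample_ids},
        condition_order=list(conditions),
        values=values,
    )


@pytest.fixture
def four_condition_matrix():
    """3 genes x 8 samples: one decreasing, one flat, one increasing."""
    rows = [
        [10, 10, 5, 5, 5, 5, 2.5, 2.5],
        [7, 7, 7, 7, 7, 7, 7, 7],
        [1, 1, 2, 2, 4, 4, 8, 8],
    ]
    return make_matrix(rows, gene_ids=["down", "flat", "up"])
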