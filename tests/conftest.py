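import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from crscore.io_formats import ExpressionMatrix


def make_expression(values, genes=None, samples=None, unit="log2"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(1, values.shape[0] + 1)]
    samples = samples or [f"s{j}" for j in range(1, values.shape[1] + 1)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), unit=unit
    )


@pytest.fixture
def five_gene_sample():
    """The hand-derived worked example: one sample, ranks 5..1 for g1..g5."""
    return make_expression(np.array([[5.0], [4.0], [3.0], [2.0], [1.0]]))


@pytest.fixture
def small_cohort():
    """A small default-condition synthetic cohort shared across tests."""
    from crscore.synthetic_data import CohortParams, simulate_cohort

    return simulate_cohort(
        CohortParams(n_genes_background=200, n_tumor=60, n_normal=20, seed=11)
    )
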