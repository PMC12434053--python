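import numpy as np
import pandas as pd
import pytest

from netsdecon import Expression, make_reference, normalize, simulate_sorted


@pytest.fixture
def toy_counts():
    """3 genes x 2 samples with simple integer counts."""
    return pd.DataFrame(
        [[1, 4], [1, 4], [2, 8]],
        index=["G1", "G2", "G3"],
        columns=["s1", "s2"],
        dtype=float,
    )


@pytest.fixture
def toy_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "donor_id": ["d1", "d2"],
            "cell_type": ["purkinje", "granule"],
            "condition": ["control", "control"],
            "age": [30, 40],
            "sex": ["F", "M"],
            "pmi": [12.0, 20.0],
            "batch": ["b1", "b1"],
        }
    )


@pytest.fixture(scope="session")
def small_reference():
    """400 genes, 8 types, 10 markers/type, boost 32 — fast for unit tests."""
    return make_reference(n_genes=400, markers_per_type=10, boost=32.0, seed=7)


@pytest.fixture(scope="session")
def sorted_cohort(small_reference):
    counts, meta, truth = simulate_sorted(small_reference, donors_per_type=3, seed=8)
    return counts, meta, truth


def log_expression(values: pd.DataFrame) -> Expression:
    """Wrap already-log-scale values as a log2_pm Expression (test helper)."""
    return Expression(values.astype(float), "log2_pm")
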