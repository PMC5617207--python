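import numpy as np
import pytest

from scqpcr.core_io import CellMeta, ExpressionMatrix, GenePanelEntry
from scqpcr.datasets import load_published_counts, published_counts_spec
from scqpcr.diff_detection import (
    detection_matrix_from_counts,
    differential_detection_table,
)
from scqpcr.synthetic import generate_dataset


def make_expr(
    values,
    populations=None,
    batches=None,
    sample_types=None,
    gene_names=None,
    categories=None,
    ceiling=35.0,
) -> ExpressionMatrix:
    """Build a small ExpressionMatrix with minimal boilerplate."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    populations = populations or ["P"] * n
    batches = batches or ["b1"] * n
    sample_types = sample_types or ["cell"] * n
    gene_names = gene_names or [f"g{j}" for j in range(g)]
    categories = categories or ["other"] * g
    cells = [
        CellMeta(f"c{i:03d}", populations[i], batches[i], sample_types[i])
        for i in range(n)
    ]
    genes = [GenePanelEntry(s, c) for s, c in zip(gene_names, categories)]
    return ExpressionMatrix(values=values, cells=cells, genes=genes,
                            ceiling=ceiling)


@pytest.fixture(scope="session")
def published_counts():
    return load_published_counts()


@pytest.fixture(scope="session")
def published_diff(published_counts):
    """The published count fixture pushed through the full Fisher+BH path."""
    d = detection_matrix_from_counts(published_counts)
    return differential_detection_table(d, "MCH", "HcrtOx", q=0.05)


@pytest.fixture(scope="session")
def synth_dataset():
    """One generated two-population dataset (study-sized, seed fixed)."""
    spec = published_counts_spec(seed=17)
    return generate_dataset(spec)
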