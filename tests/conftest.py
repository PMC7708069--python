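import numpy as np
import pytest

from transpute import ExpressionMatrix, GeneSplit


def make_matrix(
    n_samples: int,
    n_genes: int,
    seed: int = 0,
    n_datasets: int = 3,
    dated: bool = True,
    positive: bool = True,
) -> ExpressionMatrix:
    """Random matrix with round-robin dataset membership and monthly dates."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n_samples, n_genes))
    if positive:
        values += 10.0
    dates = None
    if dated:
        dates = [
            f"{2000 + (i % n_datasets) // 12:04d}-{(i % n_datasets) % 12 + 1:02d}-01"
            for i in range(n_samples)
        ]
    return ExpressionMatrix(
        values=values,
        sample_ids=[f"GSM{i}" for i in range(n_samples)],
        gene_ids=[f"G{j}" for j in range(n_genes)],
        dataset_ids=[f"DS{i % n_datasets}" for i in range(n_samples)],
        dates=dates,
    )


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return make_matrix(12, 8, seed=42)


@pytest.fixture
def gene_split(small_matrix) -> GeneSplit:
    genes = small_matrix.gene_ids
    return GeneSplit(measured=genes[:5], unmeasured=genes[5:])
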