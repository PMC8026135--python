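import numpy as np
import pandas as pd
import pytest

from regiosig.containers import CountMatrix


@pytest.fixture
def small_matrix():
    """6 genes x 6 samples, all-positive so every gene is a reference gene."""
    rng = np.random.default_rng(42)
    counts = rng.integers(1, 200, size=(6, 6))
    samples = pd.DataFrame(
        {"region": ["Th"] * 3 + ["Ctx"] * 3},
        index=[f"s{i}" for i in range(6)],
    )
    return CountMatrix(counts=counts, gene_ids=[f"g{i}" for i in range(6)],
                       samples=samples)


def make_matrix(counts, sample_meta=None):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    meta = sample_meta if sample_meta is not None else pd.DataFrame(
        index=[f"s{i}" for i in range(n_samples)]
    )
    return CountMatrix(
        counts=counts, gene_ids=[f"g{i}" for i in range(n_genes)], samples=meta
    )
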