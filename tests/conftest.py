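import numpy as np
import pytest

from anpmopso import ExpressionDataset, TrainTestSplit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(n_genes=12, n_samples=20, n_classes=2, seed=0, split=True):
    """Small labeled dataset with one informative gene, for plumbing tests."""
    r = np.random.default_rng(seed)
    labels = np.arange(n_samples) % n_classes
    values = r.normal(size=(n_genes, n_samples))
    values[0] += 3.0 * labels
    sp = None
    if split:
        idx = np.arange(n_samples)
        sp = TrainTestSplit(train=idx[::2], test=idx[1::2])
    return ExpressionDataset(
        values=values,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{i}" for i in range(n_samples)],
        labels=labels,
        split=sp,
    )


@pytest.fixture
def small_dataset():
    return make_dataset()
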