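import numpy as np
import pytest

from oveseg import ExpressionDataset


def make_dataset(values, n_k, gene_ids=None):
    """Build an ExpressionDataset from a matrix and per-subtype sizes."""
    values = np.asarray(values, dtype=float)
    K = len(n_k)
    sample_ids, subtype_of = [], {}
    for k in range(K):
        for i in range(n_k[k]):
            sid = f"S{k}_{i}"
            sample_ids.append(sid)
            subtype_of[sid] = f"S{k}"
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionDataset(
        values=values, gene_ids=gene_ids, sample_ids=sample_ids,
        subtype_of=subtype_of,
    )


@pytest.fixture
def two_group_data():
    """2 subtypes x 2 samples, hand-checkable values."""
    return make_dataset([[0.0, 2.0, 1.0, 3.0]], n_k=(2, 2))


@pytest.fixture
def gaussian_null_data():
    """3 balanced subtypes, pure Gaussian null, 200 genes."""
    rng = np.random.default_rng(11)
    return make_dataset(rng.normal(5.0, 1.0, size=(200, 12)), n_k=(4, 4, 4))
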