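import numpy as np
import pytest

from sccmgan import LabeledCounts, SyntheticSpec, make_synthetic, preprocess, split_train_test


def make_labeled(counts, gene_ids=None, types=None, subjects=None, normalized=False):
    """Compact constructor for small hand-written fixtures."""
    counts = np.asarray(counts, dtype=float)
    g, n = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    cell_ids = [f"c{i}" for i in range(n)]
    types = types or ["T"] * n
    subjects = subjects or ["S"] * n
    return LabeledCounts(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_type=dict(zip(cell_ids, types)),
        subject=dict(zip(cell_ids, subjects)),
        normalized=normalized,
    )


def heterogeneous_split(seed, subject_sigma=0.6, **spec_kw):
    """The benchmark regime: 4 subjects, 5 types, 500 genes, split 50/50."""
    data, truth = make_synthetic(
        SyntheticSpec(seed=seed, subject_sigma=subject_sigma, **spec_kw)
    )
    _, norm, _ = preprocess(data)
    return split_train_test(norm, 0.5, seed=seed), truth


@pytest.fixture(scope="session")
def small_train():
    """Preprocessed 3-type training half used by generator unit tests."""
    spec = SyntheticSpec(
        n_genes=60,
        cell_types={"A": 80, "B": 80, "C": 80},
        subjects=("S1", "S2"),
        marker_fraction=0.2,
        marker_fold=4.0,
        subject_sigma=0.2,
        seed=7,
    )
    data, _ = make_synthetic(spec)
    _, norm, _ = preprocess(data)
    return split_train_test(norm, 0.5, seed=7).train
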