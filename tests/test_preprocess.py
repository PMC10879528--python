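import numpy as np
import pytest
from scipy.stats import rankdata

from sccmgan import (
    DataError,
    QCConfig,
    SyntheticSpec,
    apply_normalization,
    cell_qc_metrics,
    filter_cells_mad,
    filter_genes_basic,
    filter_genes_prevalence,
    make_synthetic,
    preprocess,
    tmm_factors,
)
from sccmgan.preprocess import MAD_SCALE, _mad_outliers

from conftest import make_labeled


def test_filter_genes_basic_rules():
    data = make_labeled(
        [[0, 0, 0, 0],     # zero expression -> out
         [5, 5, 5, 5],     # zero variability -> out
         [0, 1, 0, 2]],    # informative -> kept
    )
    kept, removed = filter_genes_basic(data)
    assert kept.gene_ids == ["g2"]
    assert removed == ["g0", "g1"]


def test_filter_genes_basic_refuses_empty_result():
    with pytest.raises(DataError, match="empty matrix"):
        filter_genes_basic(make_labeled([[1, 1], [0, 0]]))


def test_cell_qc_metrics_arithmetic():
    data = make_labeled(
        [[10, 0], [90, 50], [0, 50]],
        gene_ids=["MT-CO1", "ACTB", "RPS4"],
    )
    m = cell_qc_metrics(data, QCConfig())
    assert m.loc["c0", "library_size"] == 100
    assert m.loc["c0", "mito_fraction"] == pytest.approx(0.10)
    assert m.loc["c0", "ribo_fraction"] == pytest.approx(0.0)
    assert m.loc["c1", "ribo_fraction"] == pytest.approx(0.5)


def test_cell_qc_metrics_without_family_genes():
    m = cell_qc_metrics(make_labeled([[5, 7]]), QCConfig())
    assert (m["mito_fraction"] == 0).all() and (m["ribo_fraction"] == 0).all()


def test_mad_rule_degenerate_and_boundary():
    # all identical: zero deviations, nothing flagged
    assert not _mad_outliers(np.full(6, 3.0), 3.0, MAD_SCALE).any()
    # crafted (exact binary arithmetic, unscaled MAD) so the last value sits
    # exactly at median + 3 * MAD: median 2, MAD 0.5, fence 1.5
    v = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 3.5])
    assert not _mad_outliers(v, 3.0, 1.0).any()            # strict inequality
    v[-1] += 1e-6
    assert _mad_outliers(v, 3.0, 1.0).tolist() == [False] * 5 + [True]


def test_library_outlier_cell_removed_exactly():
    rng = np.random.default_rng(5)
    counts = rng.poisson(20.0, size=(40, 30)).astype(float)
    counts[:, 7] *= 100  # one cell with a 100x library
    data = make_labeled(counts)
    kept, removed = filter_cells_mad(data, QCConfig())
    assert list(removed) == ["c7"]
    assert removed["c7"] == "library_size"
    assert kept.n_cells == 29


def test_prevalence_filter_boundaries():
    n = 100
    counts = np.zeros((3, n))
    counts[0, :5] = 2        # count > 1 in exactly 5% of cells -> kept
    counts[1, :] = 1         # never exceeds the detection threshold -> out
    counts[2, :4] = 10       # only 4% of cells -> out
    kept, removed = filter_genes_prevalence(make_labeled(counts), QCConfig())
    assert kept.gene_ids == ["g0"]
    assert removed == ["g1", "g2"]


# -- TMM --------------------------------------------------------------------


def _tmm_oracle(obs, ref):
    """Direct evaluation of the doubly trimmed, precision-weighted mean of M."""
    n_o, n_r = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / n_o, ref[keep] / n_r
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (1 - o) / (n_o * o) + (1 - r) / (n_r * r)
    n = len(m)
    lo_m, lo_a = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
    sel = ((rankdata(m) >= lo_m) & (rankdata(m) <= n + 1 - lo_m)
           & (rankdata(a) >= lo_a) & (rankdata(a) <= n + 1 - lo_a))
    return 2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))


def test_tmm_identities():
    rng = np.random.default_rng(1)
    col = rng.poisson(30.0, size=200).astype(float) + 1
    identical = make_labeled(np.column_stack([col, col, col]))
    f = tmm_factors(identical)
    assert all(abs(v - 1) < 1e-12 for v in f.values())

    scaled = make_labeled(np.column_stack([col, 2 * col]))
    f = tmm_factors(scaled)
    assert all(abs(v - 1) < 1e-9 for v in f.values())


def test_tmm_geometric_mean_is_one():
    rng = np.random.default_rng(2)
    data = make_labeled(rng.poisson(15.0, size=(300, 8)).astype(float) + 1)
    f = np.array(list(tmm_factors(data).values()))
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


def test_tmm_two_columns_match_brute_force():
    rng = np.random.default_rng(3)
    a = rng.poisson(rng.uniform(1, 60, 400)).astype(float)
    b = rng.poisson(rng.uniform(1, 60, 400)).astype(float)
    data = make_labeled(np.column_stack([a, b]))
    f = tmm_factors(data)
    # reference choice: 75th-percentile CPM closest to the mean
    cpm = data.counts / data.counts.sum(axis=0) * 1e6
    q75 = np.quantile(cpm, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    obs = 1 - ref
    raw = _tmm_oracle(data.counts[:, obs], data.counts[:, ref])
    expected_obs, expected_ref = np.sqrt(raw), 1 / np.sqrt(raw)
    assert f[data.cell_ids[obs]] == pytest.approx(expected_obs, abs=1e-9)
    assert f[data.cell_ids[ref]] == pytest.approx(expected_ref, abs=1e-9)


def test_apply_normalization_identity_and_scale_invariance():
    rng = np.random.default_rng(4)
    counts = rng.poisson(20.0, size=(50, 4)).astype(float) + 1
    data = make_labeled(counts)
    ones = {c: 1.0 for c in data.cell_ids}
    same = apply_normalization(make_labeled(np.tile(counts[:, :1], (1, 4))), ones)
    assert np.allclose(same.counts, np.tile(counts[:, :1], (1, 4)) /
                       1.0)  # equal libraries, factors 1 -> unchanged
    # doubling one column's counts is undone by the normalization
    doubled = counts.copy()
    doubled[:, 0] *= 2
    norm_a = apply_normalization(make_labeled(counts), ones)
    norm_b = apply_normalization(make_labeled(doubled), ones)
    ratio = norm_a.counts.sum() / norm_b.counts.sum()
    assert np.allclose(norm_b.counts[:, 0] * ratio, norm_a.counts[:, 0], rtol=1e-9)


def test_normalized_library_sizes_agree_on_no_de_fixture():
    rng = np.random.default_rng(6)
    mu = rng.uniform(5, 50, 300)
    depth = rng.uniform(0.5, 2.0, 12)
    counts = rng.poisson(mu[:, None] * depth[None, :]).astype(float)
    data = make_labeled(counts)
    norm = apply_normalization(data, tmm_factors(data))
    libs = norm.counts.sum(axis=0)
    assert libs.max() / libs.min() < 1.05


def test_pipeline_filters_nearly_idempotent():
    """Re-running the pipeline on its own output removes no further genes.

    The gene filters are exactly idempotent.  The MAD cell filter is not, by
    construction: removing the tail re-shrinks the robust fence, so a re-run
    may flag a handful of boundary cells -- we bound that effect instead.
    """
    data, _ = make_synthetic(SyntheticSpec(seed=3, outlier_cells=5))
    first, _, _ = preprocess(data, normalize=False)
    second, _, report2 = preprocess(first, normalize=False)
    assert second.gene_ids == first.gene_ids
    assert report2.genes_removed_zero == 0
    assert report2.genes_removed_prevalence == 0
    assert report2.cells_removed_qc <= 0.005 * first.n_cells


def test_qc_removes_planted_outliers():
    spec = SyntheticSpec(seed=1, subject_sigma=0.0, outlier_cells=3,
                         outlier_fold=50.0, mito_fraction_genes=0.0,
                         ribo_fraction_genes=0.0,
                         cell_types={f"type{k}": 60 for k in range(1, 6)})
    data, truth = make_synthetic(spec)
    _, removed = filter_cells_mad(data, QCConfig())
    assert set(removed) == set(truth.outlier_cell_ids)
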