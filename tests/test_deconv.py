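import json

import numpy as np
import pytest

from sccmgan import (
    DataError,
    EvalReport,
    GeneratorConfig,
    SignatureMatrix,
    build_signature,
    grid_search,
    merge_references,
    nnls_deconvolve,
    paired_ttest,
    pearson,
    rmse,
    run_benchmark,
)
from sccmgan.deconv import _evaluate
from sccmgan.pseudobulk import make_mixtures

from conftest import heterogeneous_split, make_labeled


def test_signature_is_mean_of_cpm_profiles():
    counts = np.array([[100.0, 10.0, 8.0], [300.0, 30.0, 2.0]])
    data = make_labeled(counts, types=["A", "A", "B"])
    sig = build_signature(data)
    # both A cells have the same CPM profile (0.25, 0.75) * 1e6
    assert np.allclose(sig.values[:, 0], [2.5e5, 7.5e5])
    assert np.allclose(sig.values.sum(axis=0), 1e6)
    assert sig.cell_types == ["A", "B"]


def test_augmentation_changes_only_contributed_types():
    data = make_labeled(np.array([[4.0, 1.0], [2.0, 3.0]]), types=["A", "B"])
    gen = make_labeled(np.array([[9.0], [1.0]]), types=["A"], subjects=["aug"])
    merged = merge_references(data, gen, "aug")
    before, after = build_signature(data), build_signature(merged)
    assert np.allclose(before.values[:, 1], after.values[:, 1])  # B untouched
    assert not np.allclose(before.values[:, 0], after.values[:, 0])


def test_nnls_worked_examples():
    sig = SignatureMatrix(np.array([[10.0, 0.0], [0.0, 10.0]]), ["g0", "g1"], ["A", "B"])
    assert np.allclose(nnls_deconvolve(np.array([5.0, 5.0]), sig)[:, 0], [0.5, 0.5])
    sig2 = SignatureMatrix(np.array([[8.0, 2.0], [2.0, 8.0]]), ["g0", "g1"], ["A", "B"])
    w = nnls_deconvolve(np.array([6.0, 4.0]), sig2)[:, 0]
    assert np.allclose(w, [2 / 3, 1 / 3], atol=1e-9)


def test_nnls_noiseless_identifiability():
    rng = np.random.default_rng(0)
    sig = SignatureMatrix(rng.uniform(1, 100, (40, 4)), [f"g{i}" for i in range(40)],
                          list("ABCD"))
    w_true = rng.dirichlet(np.ones(4), size=10).T
    bulk = sig.values @ w_true
    est = nnls_deconvolve(bulk, sig)
    assert np.allclose(est, w_true, atol=1e-6)


def test_nnls_gene_intersection_and_errors():
    sig = SignatureMatrix(np.array([[10.0, 0.0], [0.0, 10.0]]), ["g0", "g1"], ["A", "B"])
    est = nnls_deconvolve(np.array([5.0, 99.0, 5.0]), sig,
                          bulk_gene_ids=["g0", "gX", "g1"])
    assert np.allclose(est[:, 0], [0.5, 0.5])
    with pytest.raises(DataError, match="no genes shared"):
        nnls_deconvolve(np.array([1.0]), sig, bulk_gene_ids=["gZ"])
    with pytest.raises(DataError, match="all-zero"):
        nnls_deconvolve(np.zeros(2), sig)


def test_rmse_definitions():
    true = np.array([[0.5, 1.0], [0.5, 0.0]])
    est = np.array([[0.6, 1.0], [0.4, 0.0]])
    assert rmse(true, true, "overall") == 0.0
    per_mix = rmse(true, est, "per_mixture")
    assert per_mix == pytest.approx([0.1, 0.0])
    perm = [1, 0]
    assert rmse(true[perm], est[perm], "overall") == rmse(true, est, "overall")
    with pytest.raises(DataError, match="shape"):
        rmse(true, est[:1], "overall")


def test_pearson_affine_invariance_and_closed_form():
    true = np.array([[0.2, 0.5, 0.8], [0.8, 0.5, 0.2]])
    assert pearson(true, 3 * true + 0.1, "overall") == pytest.approx(1.0)
    # hand-computed: r of (1,2,4) against (1,3,5)
    x, y = np.array([1.0, 2.0, 4.0]), np.array([1.0, 3.0, 5.0])
    r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
              / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
    got = pearson(x[None, :], y[None, :], "per_type", ["t"])["t"]
    assert got == pytest.approx(r_hand, abs=1e-12)


def test_pearson_undefined_is_missing_not_zero():
    true = np.array([[0.5, 0.5, 0.5]])
    est = np.array([[0.1, 0.2, 0.3]])
    with pytest.warns(UserWarning, match="undefined"):
        out = pearson(true, est, "per_type", ["flat"])
    assert out["flat"] is None


def test_paired_ttest_closed_form_and_degenerate_cases():
    d = np.array([-0.1, -0.2, 0.0])
    res = paired_ttest(d, np.zeros(3))
    assert res["t_statistic"] == pytest.approx(-np.sqrt(3), abs=1e-9)
    assert res["p_value"] == pytest.approx(0.2254033, abs=1e-6)
    assert res["n_pairs"] == 3

    same = paired_ttest(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
    assert same["t_statistic"] == 0.0 and same["p_value"] == 1.0
    with pytest.raises(DataError, match="degenerate pairing"):
        paired_ttest(np.array([1.0, 1.0]), np.array([0.0, 0.0]))


def test_ttest_scale_property():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0.1, 1, 20), rng.normal(0.0, 1, 20)
    t1 = paired_ttest(a, b)["t_statistic"]
    t2 = paired_ttest(2 * a, 2 * b)["t_statistic"]  # doubles mean AND sd
    assert t1 == pytest.approx(t2, abs=1e-12)


# -- benchmark loop ----------------------------------------------------------


def test_control_run_has_no_comparison():
    split, _ = heterogeneous_split(seed=0)
    rep = run_benchmark(split.train, split.test, None, n_mixtures=30, seed=0)
    assert rep.comparison is None
    assert rep.estimated.shape[1] == 30
    assert np.allclose(rep.estimated.sum(axis=0), 1.0, atol=1e-9)
    assert np.all(rep.per_mixture_rmse >= 0)


def test_duplicating_reference_cells_leaves_metrics_unchanged():
    """A generator that emits exact copies of the training cells does not move
    the per-type mean signature, so metrics must match the control run."""
    split, _ = heterogeneous_split(seed=1)
    train, test = split.train, split.test
    pb = make_mixtures(test, 40, 100, seed=1)
    control = _evaluate(pb, build_signature(train))
    copies = make_labeled(
        train.counts.copy(),
        gene_ids=list(train.gene_ids),
        types=list(train.cell_type_array),
        subjects=["copy"] * train.n_cells,
        normalized=True,
    )
    merged = merge_references(train, copies, "copy-case")
    doubled = _evaluate(pb, build_signature(merged))
    assert doubled.overall_rmse == pytest.approx(control.overall_rmse, abs=1e-9)
    assert doubled.overall_pearson == pytest.approx(control.overall_pearson, abs=1e-9)


def test_report_round_trips_through_json(tmp_path):
    split, _ = heterogeneous_split(seed=0)
    rep = run_benchmark(split.train, split.test,
                        GeneratorConfig(backend="copula"), n_mixtures=20, seed=0)
    path = tmp_path / "report.json"
    rep.to_json(path)
    back = EvalReport.from_json(path.read_text())
    assert np.allclose(back.estimated, rep.estimated)
    assert back.comparison["pairing_unit"] == "per_mixture_rmse"
    assert back.overall_rmse == rep.overall_rmse


def test_grid_single_point_matches_direct_run():
    split, _ = heterogeneous_split(seed=2)
    template = GeneratorConfig(backend="copula")
    table = grid_search(split.train, split.test, template,
                        epochs_grid=[100], cells_grid=[50],
                        n_mixtures=20, seed=2)
    assert len(table) == 1
    direct = run_benchmark(split.train, split.test,
                           template.with_(epochs=100, cells_per_type=50),
                           n_mixtures=20, seed=2)
    assert table.loc[0, "rmse"] == pytest.approx(direct.overall_rmse)
    assert table.loc[0, "error"] is None


def test_copula_grid_is_epoch_invariant():
    """The copula has no epochs, so deltas are identical along that axis."""
    split, _ = heterogeneous_split(seed=3)
    table = grid_search(split.train, split.test, GeneratorConfig(backend="copula"),
                        epochs_grid=[50, 300], cells_grid=[40],
                        n_mixtures=20, seed=3)
    assert table.loc[0, "delta_rmse"] == table.loc[1, "delta_rmse"]
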