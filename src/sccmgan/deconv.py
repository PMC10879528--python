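"""Deconvolution of pseudo-bulk mixtures and evaluation metrics.

The baseline deconvolver builds a CPM-scale signature matrix (per-cell-type
mean of CPM profiles) and solves, per mixture, non-negative least squares

    min || S w - b ||_2   s.t.  w >= 0,

renormalizing ``w`` to the unit simplex.  Published reference-based methods
can be plugged in through :func:`read_external_proportions`, which accepts a
cell_type x mixture CSV produced by any external tool.

Evaluation mirrors the standard benchmark readout: per-mixture and overall
RMSE between estimated and known proportions, Pearson correlation per cell
type (across mixtures) and overall, and a paired t-test comparing an
augmented run against its control.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .datamodel import DataError, LabeledCounts, merge_references
from .pseudobulk import PseudoBulkSet, make_mixtures
from .generators import GeneratorConfig, fit_generator


@dataclass
class SignatureMatrix:
    """Genes x cell-types matrix of mean CPM expression."""

    values: np.ndarray
    gene_ids: List[str]
    cell_types: List[str]
    scale: str = "cpm"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.cell_types)):
            raise DataError("signature shape does not match identifiers")
        if np.any(self.values.sum(axis=0) == 0):
            raise DataError("signature has an all-zero cell-type column")


@dataclass
class EvalReport:
    estimated: np.ndarray  # (cell_types, n_mixtures)
    cell_types: List[str]
    per_mixture_rmse: np.ndarray
    per_type_pearson: Dict[str, Optional[float]]
    overall_pearson: float
    overall_rmse: float
    comparison: Optional[Dict[str, float]] = None

    def to_json(self, path=None) -> str:
        payload = {
            "cell_types": self.cell_types,
            "estimated": self.estimated.tolist(),
            "per_mixture_rmse": self.per_mixture_rmse.tolist(),
            "per_type_pearson": self.per_type_pearson,
            "overall_pearson": self.overall_pearson,
            "overall_rmse": self.overall_rmse,
            "comparison": self.comparison,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        return cls(
            estimated=np.asarray(d["estimated"]),
            cell_types=d["cell_types"],
            per_mixture_rmse=np.asarray(d["per_mixture_rmse"]),
            per_type_pearson=d["per_type_pearson"],
            overall_pearson=d["overall_pearson"],
            overall_rmse=d["overall_rmse"],
            comparison=d["comparison"],
        )


def _cpm(matrix: np.ndarray) -> np.ndarray:
    lib = matrix.sum(axis=0)
    if np.any(lib == 0):
        raise DataError("all-zero column cannot be CPM-scaled")
    return matrix / lib * 1e6


def build_signature(reference: LabeledCounts) -> SignatureMatrix:
    """Mean CPM profile per cell type, pooled over all subjects.

    Cells with zero library size (possible for degenerate generated cells)
    are dropped with a warning; a cell type whose cells sum to zero is an
    error.
    """
    if len(reference.cell_types) < 2:
        raise DataError("signature needs at least 2 cell types")
    lib = reference.library_sizes()
    if np.any(lib == 0):
        warnings.warn("dropping cells with zero library size from the signature")
        reference = reference.subset_cells(np.flatnonzero(lib > 0))
    cpm = _cpm(reference.counts)
    type_arr = reference.cell_type_array
    cols = []
    for t in reference.cell_types:
        mask = type_arr == t
        if not mask.any():
            raise DataError(f"cell type {t!r} has no usable cells")
        cols.append(cpm[:, mask].mean(axis=1))
    return SignatureMatrix(
        values=np.column_stack(cols),
        gene_ids=list(reference.gene_ids),
        cell_types=list(reference.cell_types),
    )


def nnls_deconvolve(
    bulk: np.ndarray,
    signature: SignatureMatrix,
    bulk_gene_ids: Optional[List[str]] = None,
) -> np.ndarray:
    """Estimate simplex proportions per bulk column by non-negative LS.

    ``bulk`` is genes x mixtures (a single vector is treated as one column).
    When ``bulk_gene_ids`` is given, genes are matched to the signature by
    inner join; otherwise identical gene order is assumed.
    """
    b = np.asarray(bulk, dtype=float)
    if b.ndim == 1:
        b = b[:, None]
    s = signature.values
    if bulk_gene_ids is not None:
        pos = {g: i for i, g in enumerate(signature.gene_ids)}
        common = [(i, pos[g]) for i, g in enumerate(bulk_gene_ids) if g in pos]
        if not common:
            raise DataError("no genes shared between bulk and signature")
        bi, si = zip(*common)
        b, s = b[list(bi), :], s[list(si), :]
    elif b.shape[0] != s.shape[0]:
        raise DataError("bulk and signature gene dimensions differ")

    b = _cpm(b)
    out = np.empty((s.shape[1], b.shape[1]))
    for j in range(b.shape[1]):
        w, _ = scipy.optimize.nnls(s, b[:, j])
        total = w.sum()
        if total == 0:
            raise DataError(f"NNLS returned the zero vector for mixture {j}")
        out[:, j] = w / total
    return out


def read_external_proportions(path, cell_types: List[str]) -> np.ndarray:
    """Adapter for external deconvolution tools: cell_type x mixture CSV."""
    table = pd.read_csv(path, index_col=0)
    missing = [t for t in cell_types if t not in table.index]
    if missing:
        raise DataError(f"external proportions missing cell types: {missing}")
    return table.loc[cell_types].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def rmse(true: np.ndarray, est: np.ndarray, axis: str = "overall"):
    true, est = np.asarray(true, float), np.asarray(est, float)
    if true.shape != est.shape:
        raise DataError(f"shape mismatch: {true.shape} vs {est.shape}")
    sq = (true - est) ** 2
    if axis == "per_mixture":
        return np.sqrt(sq.mean(axis=0))
    if axis == "overall":
        return float(np.sqrt(sq.mean()))
    raise DataError(f"unknown axis {axis!r}")


def pearson(true: np.ndarray, est: np.ndarray, axis: str = "overall",
            cell_types: Optional[List[str]] = None):
    """Pearson r per cell type (across mixtures) or over all entries.

    A constant vector has no defined correlation; such types are reported as
    ``None`` with a warning rather than coerced to zero.
    """
    true, est = np.asarray(true, float), np.asarray(est, float)
    if true.shape != est.shape:
        raise DataError(f"shape mismatch: {true.shape} vs {est.shape}")
    if axis == "overall":
        t, e = true.ravel(), est.ravel()
        if t.std() == 0 or e.std() == 0:
            warnings.warn("constant vector: overall Pearson undefined")
            return None
        return float(scipy.stats.pearsonr(t, e).statistic)
    if axis == "per_type":
        labels = cell_types or [f"type{i}" for i in range(true.shape[0])]
        out: Dict[str, Optional[float]] = {}
        for i, t in enumerate(labels):
            if true[i].std() == 0 or est[i].std() == 0:
                warnings.warn(f"constant proportions for {t!r}: Pearson undefined")
                out[t] = None
            else:
                out[t] = float(scipy.stats.pearsonr(true[i], est[i]).statistic)
        return out
    raise DataError(f"unknown axis {axis!r}")


def paired_ttest(metric_a: np.ndarray, metric_b: np.ndarray) -> Dict[str, float]:
    """Two-sided paired t-test of ``metric_a`` vs ``metric_b``."""
    a, b = np.asarray(metric_a, float), np.asarray(metric_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired t-test needs two equal-length vectors")
    if len(a) < 2:
        raise DataError("paired t-test needs at least 2 pairs")
    d = a - b
    if d.std() == 0:
        if d[0] == 0:  # identical vectors: no effect, conventionally t=0, p=1
            return {"t_statistic": 0.0, "p_value": 1.0, "n_pairs": len(a)}
        raise DataError("degenerate pairing: zero-variance nonzero differences")
    res = scipy.stats.ttest_rel(a, b)
    return {
        "t_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_pairs": len(a),
    }


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------


def _augment(train: LabeledCounts, generator, seed: int) -> LabeledCounts:
    """Produce generated cells from a GeneratorConfig or CMGANConfig."""
    from .cmgan import CMGANConfig, sc_cmgan_generate

    if isinstance(generator, CMGANConfig):
        cfg = CMGANConfig(**{**asdict_shallow(generator), "seed": seed})
        return sc_cmgan_generate(train, cfg)
    if isinstance(generator, GeneratorConfig):
        model = fit_generator(train, generator.with_(seed=seed))
        return model.sample(generator.cells_per_type, seed=seed)
    raise DataError(f"unsupported generator config: {type(generator).__name__}")


def asdict_shallow(cfg) -> dict:
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def _evaluate(pb: PseudoBulkSet, signature: SignatureMatrix) -> EvalReport:
    est = nnls_deconvolve(pb.mixtures, signature, bulk_gene_ids=pb.gene_ids)
    # align truth rows with signature cell types
    order = [pb.cell_types.index(t) for t in signature.cell_types]
    true = pb.proportions[order, :]
    return EvalReport(
        estimated=est,
        cell_types=list(signature.cell_types),
        per_mixture_rmse=rmse(true, est, "per_mixture"),
        per_type_pearson=pearson(true, est, "per_type", signature.cell_types),
        overall_pearson=pearson(true, est, "overall"),
        overall_rmse=rmse(true, est, "overall"),
    )


def run_benchmark(
    reference: LabeledCounts,
    test: LabeledCounts,
    generator=None,
    n_mixtures: int = 1000,
    cells_per_mixture: int = 100,
    seed: int = 0,
    concentration: float = 1.0,
    case_label: str = "augmented",
) -> EvalReport:
    """Full benchmark loop: pseudo-bulk from ``test``, deconvolve vs reference.

    With ``generator`` (a GeneratorConfig or CMGANConfig) the reference is
    augmented and the report describes the augmented run, with ``comparison``
    holding the paired per-mixture-RMSE t-test against the control run.
    Without a generator the control report is returned, ``comparison`` absent.
    """
    if set(reference.gene_ids) != set(test.gene_ids):
        raise DataError("reference and test must share the same gene set")
    pb = make_mixtures(
        test, n_mixtures=n_mixtures, cells_per_mixture=cells_per_mixture,
        seed=seed, concentration=concentration,
    )
    missing = [t for t in pb.cell_types if t not in reference.cell_types]
    if missing:
        raise DataError(f"test cell types absent from reference: {missing}")
    control = _evaluate(pb, build_signature(reference))
    if generator is None:
        return control

    generated = _augment(reference, generator, seed)
    augmented_ref = merge_references(reference, generated, case_label)
    report = _evaluate(pb, build_signature(augmented_ref))
    test_res = paired_ttest(report.per_mixture_rmse, control.per_mixture_rmse)
    report.comparison = {
        "delta_rmse": report.overall_rmse - control.overall_rmse,
        "delta_pearson": (report.overall_pearson or np.nan)
        - (control.overall_pearson or np.nan),
        "control_rmse": control.overall_rmse,
        "control_pearson": control.overall_pearson,
        "t_statistic": test_res["t_statistic"],
        "p_value": test_res["p_value"],
        "pairing_unit": "per_mixture_rmse",
    }
    return report


def grid_search(
    reference: LabeledCounts,
    test: LabeledCounts,
    generator_template,
    epochs_grid: Optional[List[int]] = None,
    cells_grid: Optional[List[int]] = None,
    n_mixtures: int = 1000,
    cells_per_mixture: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep training epochs x generated cells per type; one benchmark each.

    Returns a table with columns ``epochs, cells, rmse, pearson, delta_rmse,
    delta_pearson, p_value, error``; a failing grid point is recorded with
    its error message and does not abort the sweep.
    """
    epochs_grid = epochs_grid or list(range(50, 301, 50))
    cells_grid = cells_grid or list(range(100, 1001, 100))
    if not epochs_grid or not cells_grid:
        raise DataError("grids must be non-empty")
    rows = []
    for epochs in epochs_grid:
        for cells in cells_grid:
            gen = _with_grid_point(generator_template, epochs, cells)
            row = {"epochs": epochs, "cells": cells, "error": None}
            try:
                rep = run_benchmark(
                    reference, test, gen,
                    n_mixtures=n_mixtures, cells_per_mixture=cells_per_mixture,
                    seed=seed,
                )
                row.update(
                    rmse=rep.overall_rmse,
                    pearson=rep.overall_pearson,
                    delta_rmse=rep.comparison["delta_rmse"],
                    delta_pearson=rep.comparison["delta_pearson"],
                    p_value=rep.comparison["p_value"],
                )
            except Exception as exc:  # keep partial results
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def _with_grid_point(template, epochs: int, cells: int):
    from .cmgan import CMGANConfig

    if isinstance(template, CMGANConfig):
        d = asdict_shallow(template)
        d["generator"] = template.generator.with_(epochs=epochs)
        d["cells_per_type"] = cells
        return CMGANConfig(**d)
    if isinstance(template, GeneratorConfig):
        return template.with_(epochs=epochs, cells_per_type=cells)
    raise DataError(f"unsupported generator template: {type(template).__name__}")
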