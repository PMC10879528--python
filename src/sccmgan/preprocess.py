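"""Quality control and normalization for the single-cell reference.

The pipeline follows the standard reference-preparation recipe for
deconvolution benchmarks, in this order:

1. drop genes with zero total expression or zero variability;
2. drop cells whose library size (log scale), mitochondrial fraction or
   ribosomal fraction lies further than ``n_mads`` scaled median absolute
   deviations from the median;
3. keep only genes detected (count strictly greater than
   ``detection_threshold``) in at least ``prevalence_fraction`` of all cells,
   regardless of cell type;
4. TMM (trimmed mean of M-values) between-cell normalization, each cell
   treated as one sample.

Mitochondrial and ribosomal genes are recognized by identifier prefix
(``MT-``, ``RPS``, ``RPL`` by default), the usual convention for human gene
symbols; the prefixes are configurable for other nomenclatures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import DataError, LabeledCounts

#: consistency factor making the MAD estimate sigma for normal data
MAD_SCALE = 1.4826


@dataclass
class QCConfig:
    n_mads: float = 3.0
    prevalence_fraction: float = 0.05
    detection_threshold: float = 1.0  # strict: kept genes need count > this
    mito_prefixes: Tuple[str, ...] = ("MT-",)
    ribo_prefixes: Tuple[str, ...] = ("RPS", "RPL")
    scale_mad: bool = True  # False: raw MAD without the 1.4826 factor

    def __post_init__(self) -> None:
        if self.n_mads <= 0:
            raise ValueError("n_mads must be positive")
        if not 0.0 < self.prevalence_fraction <= 1.0:
            raise ValueError("prevalence_fraction must lie in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "QCConfig":
        d = dict(d)
        for k in ("mito_prefixes", "ribo_prefixes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class QCReport:
    genes_removed_zero: int = 0
    cells_removed_qc: int = 0
    cells_removed_ids: Dict[str, str] = field(default_factory=dict)  # id -> metric
    genes_removed_prevalence: int = 0
    tmm_factors: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def filter_genes_basic(data: LabeledCounts) -> Tuple[LabeledCounts, List[str]]:
    """Remove genes with zero total count or identical values in every cell."""
    zero = data.counts.sum(axis=1) == 0
    constant = np.all(data.counts == data.counts[:, :1], axis=1) if data.n_cells else zero
    drop = zero | constant
    if drop.all():
        raise DataError("empty matrix: every gene has zero expression or variability")
    removed = [g for g, d in zip(data.gene_ids, drop) if d]
    return data.subset_genes(np.flatnonzero(~drop)), removed


def cell_qc_metrics(data: LabeledCounts, config: QCConfig) -> pd.DataFrame:
    """Per-cell library size and mitochondrial / ribosomal count fractions.

    Cells with zero library size get fraction 0 and are left for
    :func:`filter_cells_mad` to discard.
    """
    lib = data.counts.sum(axis=0)
    genes = np.asarray(data.gene_ids)
    mito = np.zeros(len(genes), dtype=bool)
    for p in config.mito_prefixes:
        mito |= np.char.startswith(genes, p)
    ribo = np.zeros(len(genes), dtype=bool)
    for p in config.ribo_prefixes:
        ribo |= np.char.startswith(genes, p)
    safe = np.where(lib > 0, lib, 1.0)
    return pd.DataFrame(
        {
            "library_size": lib,
            "mito_fraction": data.counts[mito].sum(axis=0) / safe,
            "ribo_fraction": data.counts[ribo].sum(axis=0) / safe,
        },
        index=pd.Index(data.cell_ids, name="cell_id"),
    )


def _mad_outliers(values: np.ndarray, n_mads: float, scale: float) -> np.ndarray:
    med = np.median(values)
    mad = scale * np.median(np.abs(values - med))
    # strict inequality: a deviation exactly at the fence is retained, and a
    # zero MAD flags only cells that deviate at all
    return np.abs(values - med) > n_mads * mad


def filter_cells_mad(
    data: LabeledCounts, config: QCConfig
) -> Tuple[LabeledCounts, Dict[str, str]]:
    """Discard outlier cells by the robust three-metric MAD rule.

    Library size is assessed on log scale.  Returns the filtered data and a
    mapping ``cell_id -> first violated metric``.
    """
    if data.n_cells < 3:
        raise DataError("need at least 3 cells for MAD-based QC")
    metrics = cell_qc_metrics(data, config)
    scale = MAD_SCALE if config.scale_mad else 1.0
    removed: Dict[str, str] = {}

    zero_lib = metrics["library_size"].to_numpy() == 0
    for cid in metrics.index[zero_lib]:
        removed[cid] = "library_size"

    checks = {
        "library_size": np.log1p(metrics["library_size"].to_numpy()),
        "mito_fraction": metrics["mito_fraction"].to_numpy(),
        "ribo_fraction": metrics["ribo_fraction"].to_numpy(),
    }
    for name, values in checks.items():
        out = _mad_outliers(values, config.n_mads, scale)
        for cid in metrics.index[out]:
            removed.setdefault(cid, name)

    keep = [i for i, c in enumerate(data.cell_ids) if c not in removed]
    if not keep:
        raise DataError("cell QC removed every cell")
    return data.subset_cells(keep), removed


def filter_genes_prevalence(
    data: LabeledCounts, config: QCConfig
) -> Tuple[LabeledCounts, List[str]]:
    """Keep genes detected above threshold in enough cells, any cell type."""
    n_needed = int(np.ceil(config.prevalence_fraction * data.n_cells))
    detected = (data.counts > config.detection_threshold).sum(axis=1)
    keep = detected >= n_needed
    if not keep.any():
        raise DataError("prevalence filter removed every gene")
    removed = [g for g, k in zip(data.gene_ids, keep) if not k]
    return data.subset_genes(np.flatnonzero(keep)), removed


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, log_ratio_trim: float = 0.3, abs_expr_trim: float = 0.05
) -> float:
    """TMM factor of one column against the reference column.

    Genes zero in either sample are excluded; log-ratios (M) are trimmed 30%
    from each tail and mean log-abundances (A) 5% from each tail; the factor
    is 2 to the precision-weighted mean of the surviving M values.
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise DataError("cell shares no expressed genes with the TMM reference")
    o, r = obs[both], ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic binomial variance of M, the precision weight denominator
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    n = len(m)
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(data: LabeledCounts) -> Dict[str, float]:
    """Trimmed-mean-of-M-values scaling factor per cell (columns as samples).

    The reference cell is the one whose 75th-percentile CPM is closest to the
    mean 75th-percentile CPM; factors are rescaled to geometric mean 1.
    """
    if data.n_cells < 2:
        raise DataError("TMM needs at least 2 cells")
    lib = data.library_sizes()
    if np.any(lib <= 0):
        raise DataError("TMM requires positive library sizes")
    cpm = data.counts / lib * 1e6
    q75 = np.quantile(cpm, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = data.counts[:, ref_idx]

    raw = np.array(
        [
            1.0 if j == ref_idx else _tmm_pair(data.counts[:, j], ref)
            for j in range(data.n_cells)
        ]
    )
    raw /= np.exp(np.mean(np.log(raw)))  # geometric mean 1
    return {c: float(f) for c, f in zip(data.cell_ids, raw)}


def apply_normalization(data: LabeledCounts, factors: Dict[str, float]) -> LabeledCounts:
    """Divide each column by its effective library size relative to the mean.

    The effective size is ``library_size * factor``; dividing by its ratio to
    the mean library size keeps values on the original count scale.
    """
    missing = [c for c in data.cell_ids if c not in factors]
    if missing:
        raise DataError(f"missing TMM factor for cells: {missing[:5]}")
    lib = data.library_sizes()
    f = np.array([factors[c] for c in data.cell_ids])
    eff = lib * f / lib.mean()
    return replace(data, counts=data.counts / eff, normalized=True)


def preprocess(
    data: LabeledCounts, config: QCConfig | None = None, normalize: bool = True
) -> Tuple[LabeledCounts, LabeledCounts, QCReport]:
    """Run the full pipeline; returns ``(filtered_raw, normalized, report)``.

    ``filtered_raw`` has passed all three filters but keeps original count
    values (used for pseudo-bulk summation); ``normalized`` additionally has
    TMM normalization applied (used for signatures and marker selection).
    With ``normalize=False`` both returned datasets are the filtered counts.
    """
    config = config or QCConfig()
    report = QCReport()
    data, removed_genes = filter_genes_basic(data)
    report.genes_removed_zero = len(removed_genes)
    data, removed_cells = filter_cells_mad(data, config)
    report.cells_removed_qc = len(removed_cells)
    report.cells_removed_ids = removed_cells
    data, removed_prev = filter_genes_prevalence(data, config)
    report.genes_removed_prevalence = len(removed_prev)
    if not normalize:
        return data, data, report
    factors = tmm_factors(data)
    report.tmm_factors = factors
    return data, apply_normalization(data, factors), report
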