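"""Gaussian copula backend.

One copula per cell type: per-gene empirical marginals coupled through the
correlation matrix of normal scores (van der Waerden transform with midpoint
ranks).  Sampling draws a multivariate normal, maps coordinates to uniforms
and inverts each empirical marginal by linear interpolation between order
statistics, so generated values always stay inside the training range.
Non-positive-definite correlation matrices are repaired by clipping
eigenvalues at 1e-6 and renormalizing the diagonal.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy.stats import norm, rankdata

from ..datamodel import DataError, LabeledCounts
from .base import GeneratorConfig, GeneratorModel, _check_fit_input

_EIG_FLOOR = 1e-6


def nearest_correlation(corr: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair with unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= floor:
        return corr
    fixed = (vecs * np.clip(vals, floor, None)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _normal_scores(x_cg: np.ndarray) -> np.ndarray:
    """Column-wise van der Waerden scores with midpoint (average) ranks."""
    n = x_cg.shape[0]
    ranks = np.apply_along_axis(rankdata, 0, x_cg)
    return norm.ppf((ranks - 0.5) / n)


class CopulaModel(GeneratorModel):
    backend = "copula"

    def __init__(self, gene_ids, cell_types, config,
                 marginals: Dict[str, np.ndarray], chol: Dict[str, np.ndarray]):
        super().__init__(gene_ids, cell_types, config)
        self._marginals = marginals  # type -> (n_cells, n_genes) sorted columns
        self._chol = chol  # type -> Cholesky factor of repaired correlation

    @classmethod
    def fit(cls, train: LabeledCounts, config: GeneratorConfig) -> "CopulaModel":
        by_type = _check_fit_input(train)
        marginals, chol = {}, {}
        for t, idx in by_type.items():
            x = train.counts[:, idx].T  # cells x genes
            marginals[t] = np.sort(x, axis=0)
            z = _normal_scores(x)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(z, rowvar=False)
            corr = np.atleast_2d(corr)
            corr[~np.isfinite(corr)] = 0.0  # constant genes: uncorrelated
            np.fill_diagonal(corr, 1.0)
            chol[t] = np.linalg.cholesky(nearest_correlation(corr))
        return cls(train.gene_ids, train.cell_types, config, marginals, chol)

    def _sample_type(self, cell_type: str, n: int, rng: np.random.Generator) -> np.ndarray:
        if cell_type not in self._marginals:
            raise DataError(f"unknown cell type {cell_type!r}")
        sorted_vals = self._marginals[cell_type]
        n_train, n_genes = sorted_vals.shape
        z = rng.standard_normal((n, n_genes)) @ self._chol[cell_type].T
        u = norm.cdf(z)
        probs = (np.arange(1, n_train + 1) - 0.5) / n_train
        out = np.empty((n, n_genes))
        for g in range(n_genes):
            out[:, g] = np.interp(u[:, g], probs, sorted_vals[:, g])
        return out
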