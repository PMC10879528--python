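"""Artificial pseudo-bulk mixtures with known cell-type composition.

Each mixture is the element-wise sum of the count vectors of individually
sampled cells, so the true cell-type proportions of every mixture are known
exactly -- this is the matrix-T side of the deconvolution benchmark.
Compositions are drawn from a symmetric Dirichlet over the cell types and the
fixed per-mixture cell budget is allocated multinomially, so recorded ground
truth is the *realized* fraction of drawn cells, not the Dirichlet draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .datamodel import DataError, LabeledCounts


@dataclass
class PseudoBulkSet:
    """Genes x mixtures summed counts plus their ground-truth composition."""

    mixtures: np.ndarray  # (n_genes, n_mixtures)
    proportions: np.ndarray  # (n_cell_types, n_mixtures), columns sum to 1
    gene_ids: List[str]
    cell_types: List[str]
    cells_per_mixture: int
    seed: int

    @property
    def n_mixtures(self) -> int:
        return self.mixtures.shape[1]

    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cols = [f"mix{i}" for i in range(self.n_mixtures)]
        pd.DataFrame(self.mixtures, index=self.gene_ids, columns=cols).rename_axis(
            "gene_id"
        ).to_csv(directory / "mixtures.csv", float_format="%.17g")
        pd.DataFrame(self.proportions, index=self.cell_types, columns=cols).rename_axis(
            "cell_type"
        ).to_csv(directory / "proportions.csv", float_format="%.17g")
        manifest = {
            "cells_per_mixture": self.cells_per_mixture,
            "seed": self.seed,
            "n_mixtures": self.n_mixtures,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def make_mixtures(
    test: LabeledCounts,
    n_mixtures: int = 1000,
    cells_per_mixture: int = 100,
    seed: int = 0,
    concentration: float = 1.0,
) -> PseudoBulkSet:
    """Build ``n_mixtures`` pseudo-bulk samples from the test-half cells.

    For every mixture a composition is drawn from
    ``Dirichlet(concentration, ..., concentration)`` over the test cell
    types, ``cells_per_mixture`` cells are allocated multinomially and
    sampled with replacement within each type, and their raw count vectors
    are summed.  Deterministic given ``seed``.
    """
    if cells_per_mixture < 1:
        raise DataError("cells_per_mixture must be at least 1")
    if n_mixtures < 1:
        raise DataError("n_mixtures must be at least 1")
    if concentration <= 0:
        raise DataError("concentration must be positive")
    types = test.cell_types
    if not types:
        raise DataError("test set has no cells")
    type_arr = test.cell_type_array
    by_type = {t: np.flatnonzero(type_arr == t) for t in types}

    rng = np.random.default_rng(seed)
    k = len(types)
    mixtures = np.zeros((test.n_genes, n_mixtures))
    proportions = np.zeros((k, n_mixtures))
    for j in range(n_mixtures):
        p = rng.dirichlet(np.full(k, float(concentration)))
        alloc = rng.multinomial(cells_per_mixture, p)
        for ti, t in enumerate(types):
            if alloc[ti] == 0:
                continue
            chosen = rng.choice(by_type[t], size=alloc[ti], replace=True)
            mixtures[:, j] += test.counts[:, chosen].sum(axis=1)
        proportions[:, j] = alloc / cells_per_mixture
    return PseudoBulkSet(
        mixtures=mixtures,
        proportions=proportions,
        gene_ids=list(test.gene_ids),
        cell_types=list(types),
        cells_per_mixture=cells_per_mixture,
        seed=seed,
    )


def mixture_ground_truth(pb: PseudoBulkSet) -> np.ndarray:
    """The realized cell-type proportion matrix (cell_types x mixtures)."""
    return pb.proportions
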