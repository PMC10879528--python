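"""Shared contract for the generative backends.

Every backend is fitted on a labelled reference and can then emit a fixed
number of synthetic cells *per training cell type*, labelled with that type
and a synthetic subject.  The neural backends (GAN, VAE) train on
``log1p`` expression min-max scaled per gene to ``[-1, 1]``; samples are
mapped back through the inverse transform and clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..datamodel import DataError, LabeledCounts


@dataclass
class GeneratorConfig:
    backend: str = "gan"  # copula | gan | vae
    epochs: int = 100
    cells_per_type: int = 100
    latent_dim: int = 16
    hidden_dims: Tuple[int, ...] = (128,)
    batch_size: int = 32
    learning_rate: float = 2e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("copula", "gan", "vae"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend in ("gan", "vae") and self.epochs < 1:
            raise ValueError("epochs must be >= 1 for gan/vae backends")
        if self.cells_per_type < 1:
            raise ValueError("cells_per_type must be >= 1")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


class GeneratorModel:
    """Fitted generative backend; subclasses implement ``_sample_type``."""

    backend: str

    def __init__(self, gene_ids: List[str], cell_types: List[str],
                 config: GeneratorConfig, loss_trace: Optional[List[float]] = None):
        self.gene_ids = list(gene_ids)
        self.cell_types = list(cell_types)
        self.config = config
        self.loss_trace = loss_trace or []

    def _sample_type(self, cell_type: str, n: int,
                     rng: np.random.Generator) -> np.ndarray:  # (n, genes)
        raise NotImplementedError

    def sample(self, cells_per_type: int, seed: int,
               subject_label: str = "generated") -> LabeledCounts:
        """Generate ``cells_per_type`` cells for every training cell type."""
        if cells_per_type < 1:
            raise DataError("cells_per_type must be >= 1")
        rng = np.random.default_rng(seed)
        blocks, cell_ids, ctype = [], [], {}
        for t in self.cell_types:
            x = self._sample_type(t, cells_per_type, rng)
            x = np.maximum(x, 0.0)
            blocks.append(x.T)  # genes x cells
            for i in range(cells_per_type):
                cid = f"{subject_label}|{t}|{i}"
                cell_ids.append(cid)
                ctype[cid] = t
        counts = np.concatenate(blocks, axis=1)
        return LabeledCounts(
            counts=counts,
            gene_ids=list(self.gene_ids),
            cell_ids=cell_ids,
            cell_type=ctype,
            subject={c: subject_label for c in cell_ids},
            normalized=True,
        )


def sample_cells(model: GeneratorModel, cells_per_type: int, seed: int,
                 subject_label: str = "generated") -> LabeledCounts:
    return model.sample(cells_per_type, seed, subject_label)


@dataclass
class MinMaxLog1p:
    """``log1p`` then per-gene min-max to [-1, 1]; inverse clamps at 0."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, counts_gc: np.ndarray) -> "MinMaxLog1p":
        l = np.log1p(counts_gc)
        return cls(lo=l.min(axis=1), hi=l.max(axis=1))

    def transform(self, counts_gc: np.ndarray) -> np.ndarray:
        """genes x cells counts -> cells x genes values in [-1, 1]."""
        l = np.log1p(counts_gc)
        span = self.hi - self.lo
        with np.errstate(invalid="ignore", divide="ignore"):
            t = 2.0 * (l - self.lo[:, None]) / span[:, None] - 1.0
        t[span == 0, :] = 0.0  # constant genes sit at the centre
        return t.T

    def inverse(self, t_cg: np.ndarray) -> np.ndarray:
        """cells x genes in [-1, 1] -> cells x genes non-negative expression."""
        t = np.clip(t_cg, -1.0, 1.0)
        span = self.hi - self.lo
        l = (t + 1.0) / 2.0 * span[None, :] + self.lo[None, :]
        l[:, span == 0] = self.lo[span == 0]
        return np.maximum(np.expm1(l), 0.0)


def _check_fit_input(train: LabeledCounts) -> Dict[str, np.ndarray]:
    """Validate and index training cells by type (>= 2 cells per type)."""
    type_arr = train.cell_type_array
    by_type = {t: np.flatnonzero(type_arr == t) for t in train.cell_types}
    thin = [t for t, idx in by_type.items() if len(idx) < 2]
    if thin:
        raise DataError(f"cell types with fewer than 2 cells: {thin}")
    return by_type


def fit_generator(train: LabeledCounts, config: GeneratorConfig) -> GeneratorModel:
    """Fit the configured backend on the training reference."""
    from .copula import CopulaModel
    from .gan import GANModel
    from .vae import VAEModel

    cls = {"copula": CopulaModel, "gan": GANModel, "vae": VAEModel}[config.backend]
    return cls.fit(train, config)
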