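"""sc-CMGAN: stepwise marker-restricted generation with median imputation.

The method augments a single-cell reference in three phases:

1. **Feature selection** -- a ridge-penalized one-vs-rest linear model per
   cell type scores every gene; the importance of a gene is the largest
   absolute ridge coefficient it attains across cell types.  Scores are
   computed once, before any stepping.
2. **Stepwise generation** -- for step ``k = 1..n_steps`` the top
   ``t0 - (k-1)*t_step`` percent of genes by importance form the marker set
   (the sets are nested because the ranking is fixed); a generative backend
   is trained on the marker submatrix only and sampled, while every
   non-marker gene of a generated cell is assigned the per-cell-type median
   of the training expression.
3. **Combination** -- the per-step outputs are concatenated into one
   augmented case; the requested cells per type are split as evenly as
   possible across steps, remainder to the earliest steps.

Restricting the generator to a shrinking marker fraction and pinning the
remaining genes at robust per-type medians is what makes the output stable
across training epochs: most coordinates do not depend on the adversarial
fit at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Set

import numpy as np
from sklearn.linear_model import Ridge

from .datamodel import DataError, LabeledCounts
from .generators import GeneratorConfig, fit_generator


@dataclass
class CMGANConfig:
    """Hyperparameters: ``n_steps`` selection cycles starting at ``t0`` percent
    of genes and shrinking by ``t_step`` percent per cycle (default 2 cycles,
    40% then 20%)."""

    n_steps: int = 2
    t0: float = 40.0
    t_step: float = 20.0
    ridge_alpha: float = 1.0
    generator: GeneratorConfig = field(default_factory=lambda: GeneratorConfig(backend="gan"))
    cells_per_type: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.ridge_alpha <= 0:
            raise ValueError("ridge_alpha must be positive")
        if self.cells_per_type < 1:
            raise ValueError("cells_per_type must be >= 1")
        for f in self.fractions():
            if not 0.0 < f <= 100.0:
                raise ValueError(
                    f"marker fraction schedule {self.fractions()} leaves the "
                    f"(0, 100] range; reduce n_steps or t_step"
                )

    def fractions(self) -> List[float]:
        return [self.t0 - k * self.t_step for k in range(self.n_steps)]


@dataclass
class MarkerSelection:
    """Fixed importance scores plus the nested per-step marker sets."""

    importance: Dict[str, float]
    steps: List[List[str]]  # ordered by descending importance within each step
    fractions: List[float]


def rank_gene_importance(train: LabeledCounts, ridge_alpha: float = 1.0) -> Dict[str, float]:
    """Score genes by their largest absolute one-vs-rest ridge coefficient.

    Expression is log1p-transformed and per-gene standardized internally; the
    response for each cell type is its 0/1 indicator.  A high score means the
    gene discriminates at least one cell type from the rest.
    """
    types = train.cell_types
    if len(types) < 2:
        raise DataError("marker ranking needs at least 2 cell types")
    x = np.log1p(train.counts.T)  # cells x genes
    sd = x.std(axis=0)
    if np.all(sd == 0):
        raise DataError("degenerate design: all genes constant")
    sd_safe = np.where(sd > 0, sd, 1.0)
    x = (x - x.mean(axis=0)) / sd_safe
    x[:, sd == 0] = 0.0

    type_arr = train.cell_type_array
    scores = np.zeros(train.n_genes)
    for t in types:
        y = (type_arr == t).astype(float)
        model = Ridge(alpha=ridge_alpha, fit_intercept=True)
        model.fit(x, y)
        scores = np.maximum(scores, np.abs(model.coef_))
    return {g: float(s) for g, s in zip(train.gene_ids, scores)}


def marker_schedule(
    config: CMGANConfig, n_genes: int, importance: Dict[str, float]
) -> MarkerSelection:
    """Materialize the per-step marker sets from fixed importance scores.

    ``steps[k]`` holds the top ``round(fractions[k]/100 * n_genes)`` genes;
    ties are broken by input gene order, so the sets are nested.
    """
    gene_ids = list(importance.keys())
    if n_genes != len(gene_ids):
        raise DataError("n_genes does not match the importance mapping")
    fractions = config.fractions()
    scores = np.array([importance[g] for g in gene_ids])
    order = np.argsort(-scores, kind="stable")  # stable: ties keep input order
    steps = []
    for f in fractions:
        size = int(np.floor(f / 100.0 * n_genes + 0.5))
        if size < 1:
            raise DataError(f"marker fraction {f}% selects no genes out of {n_genes}")
        steps.append([gene_ids[i] for i in order[:size]])
    return MarkerSelection(importance=dict(importance), steps=steps, fractions=fractions)


def _per_type_medians(train: LabeledCounts) -> Dict[str, np.ndarray]:
    type_arr = train.cell_type_array
    return {
        t: np.median(train.counts[:, type_arr == t], axis=1)
        for t in train.cell_types
    }


def generate_step(
    train: LabeledCounts,
    markers: Sequence[str],
    generator: GeneratorConfig,
    n_cells_per_type: int,
    seed: int,
    subject_label: str = "sc-cmgan",
) -> LabeledCounts:
    """One sc-CMGAN cycle: generate markers, median-fill the rest.

    The backend is fitted on the marker submatrix only; each generated cell
    gets the per-cell-type median of the training expression at every
    non-marker gene (the median of the observed values, a scale on which the
    fill is exactly reproducible).
    """
    marker_set: Set[str] = set(markers)
    if not marker_set:
        raise DataError("empty marker set")
    unknown = marker_set - set(train.gene_ids)
    if unknown:
        raise DataError(f"markers absent from training genes: {sorted(unknown)[:5]}")

    marker_idx = [i for i, g in enumerate(train.gene_ids) if g in marker_set]
    sub = train.subset_genes(marker_idx)
    model = fit_generator(sub, generator.with_(seed=seed))
    gen = model.sample(n_cells_per_type, seed=seed, subject_label=subject_label)

    medians = _per_type_medians(train)
    counts = np.empty((train.n_genes, gen.n_cells))
    non_marker = np.array([g not in marker_set for g in train.gene_ids])
    for j, cid in enumerate(gen.cell_ids):
        counts[:, j] = medians[gen.cell_type[cid]]
    counts[marker_idx, :] = gen.counts
    return replace(
        gen,
        counts=counts,
        gene_ids=list(train.gene_ids),
    )


def sc_cmgan_generate(
    train: LabeledCounts,
    config: CMGANConfig,
    subject_label: str = "sc-cmgan",
    return_selection: bool = False,
):
    """Full sc-CMGAN augmentation: returns the generated cells as one new case.

    The requested ``cells_per_type`` is split across the ``n_steps`` cycles
    (earliest cycles take the remainder); each cycle retrains the backend on
    its own marker set.  Deterministic given ``config.seed``.
    """
    importance = rank_gene_importance(train, config.ridge_alpha)
    selection = marker_schedule(config, train.n_genes, importance)

    base, rem = divmod(config.cells_per_type, config.n_steps)
    per_step = [base + (1 if k < rem else 0) for k in range(config.n_steps)]

    blocks: List[LabeledCounts] = []
    for k, (markers, n_cells) in enumerate(zip(selection.steps, per_step)):
        if n_cells == 0:
            continue
        blocks.append(
            generate_step(
                train,
                markers,
                config.generator,
                n_cells,
                seed=config.seed + k,
                subject_label=f"{subject_label}|step{k + 1}",
            )
        )

    cell_ids, ctype, subj = [], {}, {}
    for b in blocks:
        for c in b.cell_ids:
            cell_ids.append(c)
            ctype[c] = b.cell_type[c]
            subj[c] = subject_label
    out = LabeledCounts(
        counts=np.concatenate([b.counts for b in blocks], axis=1),
        gene_ids=list(train.gene_ids),
        cell_ids=cell_ids,
        cell_type=ctype,
        subject=subj,
        normalized=train.normalized,
    )
    if return_selection:
        return out, selection
    return out


def export_marker_sets(selection: MarkerSelection, path) -> None:
    """Write a two-column TSV (gene_id, deepest step containing the gene)."""
    deepest: Dict[str, int] = {}
    for k, step in enumerate(selection.steps, start=1):
        for g in step:
            deepest[g] = k
    with open(path, "w") as fh:
        fh.write("gene_id\tstep\n")
        for g, k in deepest.items():
            fh.write(f"{g}\t{k}\n")
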