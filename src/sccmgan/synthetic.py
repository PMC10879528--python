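"""Synthetic labelled scRNA-seq data with known ground truth.

The generator emulates the data regime the pipeline is built for: several
cell types with planted marker genes, several subjects with multiplicative
between-subject expression heterogeneity, negative-binomial counts, and
mitochondrial/ribosomal gene families for QC.  Every planted feature is
recorded in a :class:`GroundTruth` so downstream stages can be tested
against the exact quantities the data were drawn from.

Model, per gene ``g``, cell type ``t``, subject ``s``::

    mu[g, t, s] = base[g] * fold[g, t] * effect[g, s]
    count ~ NegativeBinomial(mean=mu, dispersion=alpha)   var = mu + alpha mu^2

``base`` is log-uniform over ``nb_mean_range``; ``fold`` is ``marker_fold``
for a type's planted markers and 1 elsewhere; ``effect`` is log-normal with
log-scale standard deviation ``subject_sigma`` (the knob controlling how far
reference subjects sit from pseudo-bulk subjects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .datamodel import DataError, LabeledCounts
from .deconv import SignatureMatrix


@dataclass
class SyntheticSpec:
    n_genes: int = 500
    cell_types: Dict[str, int] = field(
        default_factory=lambda: {f"type{k}": 120 for k in range(1, 6)}
    )
    subjects: Tuple[str, ...] = ("S1", "S2", "S3", "S4")
    nb_mean_range: Tuple[float, float] = (0.5, 50.0)
    nb_dispersion: float = 0.3
    marker_fraction: float = 0.2
    marker_fold: float = 4.0
    subject_sigma: float = 0.3
    mito_fraction_genes: float = 0.02
    ribo_fraction_genes: float = 0.05
    outlier_cells: int = 0
    outlier_fold: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or not self.cell_types or not self.subjects:
            raise ValueError("need at least one gene, cell type and subject")
        if min(self.cell_types.values()) < 1:
            raise ValueError("every cell type needs at least one cell")
        if not 0 <= self.marker_fraction <= 1:
            raise ValueError("marker_fraction must lie in [0, 1]")
        for frac in (self.mito_fraction_genes, self.ribo_fraction_genes):
            if not 0 <= frac <= 1:
                raise ValueError("gene-family fractions must lie in [0, 1]")
        if self.subject_sigma < 0:
            raise ValueError("subject_sigma must be >= 0")
        if self.nb_mean_range[0] <= 0 or self.nb_mean_range[1] < self.nb_mean_range[0]:
            raise ValueError("nb_mean_range must be a positive interval")
        n_markers = int(round(self.marker_fraction * self.n_genes))
        if n_markers > self.n_genes:
            raise ValueError("more marker genes than genes")


@dataclass
class GroundTruth:
    spec: SyntheticSpec
    gene_ids: List[str]
    base_mean: np.ndarray  # (genes,)
    fold: np.ndarray  # (genes, types)
    subject_effect: np.ndarray  # (genes, subjects)
    markers: Dict[str, List[str]]  # type -> planted marker gene ids
    outlier_cell_ids: List[str]
    cell_types: List[str]
    subjects: List[str]

    def expected_mean(self, cell_type: str, subject: str) -> np.ndarray:
        ti = self.cell_types.index(cell_type)
        si = self.subjects.index(subject)
        return self.base_mean * self.fold[:, ti] * self.subject_effect[:, si]


def make_synthetic(spec: SyntheticSpec) -> Tuple[LabeledCounts, GroundTruth]:
    """Draw a labelled count matrix and the ground truth it came from."""
    rng = np.random.default_rng(spec.seed)
    types = list(spec.cell_types)
    subjects = list(spec.subjects)
    g, k, s = spec.n_genes, len(types), len(subjects)

    # gene names: mito / ribo families first, generic symbols after
    n_mito = int(round(spec.mito_fraction_genes * g))
    n_ribo = int(round(spec.ribo_fraction_genes * g))
    if n_mito + n_ribo > g:
        raise DataError("mito + ribo gene families exceed the gene count")
    gene_ids = (
        [f"MT-G{i}" for i in range(n_mito)]
        + [f"RPS{i}" if i % 2 == 0 else f"RPL{i}" for i in range(n_ribo)]
        + [f"G{i}" for i in range(g - n_mito - n_ribo)]
    )

    lo, hi = spec.nb_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=g))

    # planted type-specific markers: disjoint blocks drawn from the generic genes
    fold = np.ones((g, k))
    n_markers = int(round(spec.marker_fraction * g))
    candidates = rng.permutation(np.arange(n_mito + n_ribo, g))
    if n_markers > len(candidates):
        raise DataError("marker_fraction exceeds the non-family gene pool")
    marker_idx = candidates[:n_markers]
    markers: Dict[str, List[str]] = {t: [] for t in types}
    for j, gi in enumerate(marker_idx):
        t = j % k
        fold[gi, t] = spec.marker_fold
        markers[types[t]].append(gene_ids[gi])

    effect = np.exp(rng.normal(0.0, spec.subject_sigma, size=(g, s)))

    # assemble cells: per type, spread across subjects as evenly as possible
    cols, cell_ids, ctype_map, subj_map = [], [], {}, {}
    alpha = spec.nb_dispersion
    for ti, t in enumerate(types):
        n_cells = spec.cell_types[t]
        per_subj = [n_cells // s + (1 if i < n_cells % s else 0) for i in range(s)]
        for si, (subj, n_sub) in enumerate(zip(subjects, per_subj)):
            if n_sub == 0:
                continue
            mu = base * fold[:, ti] * effect[:, si]
            if alpha > 0:
                r = 1.0 / alpha
                p = r / (r + mu)
                block = rng.negative_binomial(r, p[:, None], size=(g, n_sub))
            else:
                block = rng.poisson(mu[:, None], size=(g, n_sub))
            cols.append(block.astype(np.float64))
            for i in range(n_sub):
                cid = f"{subj}|{t}|{i}"
                cell_ids.append(cid)
                ctype_map[cid] = t
                subj_map[cid] = subj

    counts = np.concatenate(cols, axis=1)

    outlier_ids: List[str] = []
    if spec.outlier_cells > 0:
        chosen = rng.choice(counts.shape[1], size=spec.outlier_cells, replace=False)
        for j in chosen:
            counts[:, j] = np.round(counts[:, j] * spec.outlier_fold)
            outlier_ids.append(cell_ids[j])

    data = LabeledCounts(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_type=ctype_map,
        subject=subj_map,
    )
    truth = GroundTruth(
        spec=spec,
        gene_ids=gene_ids,
        base_mean=base,
        fold=fold,
        subject_effect=effect,
        markers=markers,
        outlier_cell_ids=outlier_ids,
        cell_types=types,
        subjects=subjects,
    )
    return data, truth


def ground_truth_signature(truth: GroundTruth, subject: str) -> SignatureMatrix:
    """Exact expected CPM profile per cell type for one subject."""
    if subject not in truth.subjects:
        raise DataError(f"unknown subject {subject!r}")
    cols = []
    for t in truth.cell_types:
        mu = truth.expected_mean(t, subject)
        cols.append(mu / mu.sum() * 1e6)
    return SignatureMatrix(
        values=np.column_stack(cols),
        gene_ids=list(truth.gene_ids),
        cell_types=list(truth.cell_types),
    )
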