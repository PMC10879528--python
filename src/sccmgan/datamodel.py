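"""Core data containers and I/O for labelled single-cell count matrices.

The central object is :class:`LabeledCounts`: a dense genes x cells matrix of
non-negative expression values together with per-cell ``cell_type`` and
``subject`` annotations.  It is the deconvolution reference matrix (often
called matrix C) before and after augmentation.

Matrices are read and written in three plain-text layouts:

* ``mtx`` -- MatrixMarket sparse matrix with ``<stem>.genes.tsv`` and
  ``<stem>.cells.tsv`` sidecars, one identifier per line;
* ``csv`` / ``tsv`` -- dense table, genes as rows, cells as columns, first
  column holds the gene identifier.

Cell labels always travel in a separate TSV with header
``cell_id  cell_type  subject``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class DataError(ValueError):
    """Raised for malformed or inconsistent count/label inputs."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise DataError(f"duplicate {what} identifiers: {sorted(dups)[:5]}")


@dataclass
class LabeledCounts:
    """Genes x cells expression matrix with per-cell type and subject labels.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` array of finite, non-negative values.  Raw
        data are integer counts; normalized data are continuous.
    gene_ids, cell_ids
        Ordered, unique identifiers for rows and columns.
    cell_type, subject
        Mappings ``cell_id -> label``; every cell must appear in both.
    normalized
        True once between-cell normalization has been applied.
    """

    counts: np.ndarray
    gene_ids: List[str]
    cell_ids: List[str]
    cell_type: Dict[str, str]
    subject: Dict[str, str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.counts.ndim != 2:
            raise DataError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.counts)):
            raise DataError("counts contain non-finite values")
        if self.counts.size and self.counts.min() < 0:
            raise DataError("counts contain negative values")
        for c in self.cell_ids:
            if c not in self.cell_type:
                raise DataError(f"unlabeled cell: {c!r} missing cell_type")
            if c not in self.subject:
                raise DataError(f"unlabeled cell: {c!r} missing subject")

    # -- convenience accessors -------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_type_array(self) -> np.ndarray:
        return np.array([self.cell_type[c] for c in self.cell_ids])

    @property
    def subject_array(self) -> np.ndarray:
        return np.array([self.subject[c] for c in self.cell_ids])

    @property
    def cell_types(self) -> List[str]:
        """Unique cell-type labels in order of first appearance."""
        return list(dict.fromkeys(self.cell_type[c] for c in self.cell_ids))

    @property
    def subjects(self) -> List[str]:
        """Unique subject labels in order of first appearance."""
        return list(dict.fromkeys(self.subject[c] for c in self.cell_ids))

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_genes(self, index: Sequence[int]) -> "LabeledCounts":
        index = np.asarray(index, dtype=int)
        return replace(
            self,
            counts=self.counts[index, :],
            gene_ids=[self.gene_ids[i] for i in index],
        )

    def subset_cells(self, index: Sequence[int]) -> "LabeledCounts":
        index = np.asarray(index, dtype=int)
        cells = [self.cell_ids[i] for i in index]
        return replace(
            self,
            counts=self.counts[:, index],
            cell_ids=cells,
            cell_type={c: self.cell_type[c] for c in cells},
            subject={c: self.subject[c] for c in cells},
        )

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "cell_type": [self.cell_type[c] for c in self.cell_ids],
                "subject": [self.subject[c] for c in self.cell_ids],
            }
        )


@dataclass
class SplitResult:
    """Train/test partition of a :class:`LabeledCounts`."""

    train: LabeledCounts
    test: LabeledCounts


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("mtx", "csv", "tsv")


def _read_labels(labels_path: Path) -> pd.DataFrame:
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    required = {"cell_id", "cell_type", "subject"}
    if not required.issubset(labels.columns):
        raise DataError(
            f"labels table must have columns {sorted(required)}, "
            f"got {list(labels.columns)}"
        )
    return labels


def read_counts(path, format: str, labels_path) -> LabeledCounts:
    """Read a count matrix plus its label table into a :class:`LabeledCounts`.

    ``mtx`` expects ``<stem>.genes.tsv`` / ``<stem>.cells.tsv`` next to the
    matrix file; dense formats carry identifiers in the table itself.
    """
    path, labels_path = Path(path), Path(labels_path)
    if format not in _FORMATS:
        raise DataError(f"unknown format {format!r}; choose from {_FORMATS}")
    if format == "mtx":
        mat = scipy.io.mmread(str(path))
        counts = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
        )
        stem = path.with_suffix("")
        gene_ids = Path(f"{stem}.genes.tsv").read_text().split()
        cell_ids = Path(f"{stem}.cells.tsv").read_text().split()
    else:
        sep = "," if format == "csv" else "\t"
        table = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        counts = table.to_numpy(dtype=np.float64)
        gene_ids = [str(g) for g in table.index]
        cell_ids = [str(c) for c in table.columns]

    labels = _read_labels(labels_path).set_index("cell_id")
    if labels.index.has_duplicates:
        raise DataError("duplicate cell_id rows in labels table")
    missing = [c for c in cell_ids if c not in labels.index]
    if missing:
        raise DataError(f"unlabeled cell: {missing[:5]} absent from labels table")
    return LabeledCounts(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_type={c: labels.at[c, "cell_type"] for c in cell_ids},
        subject={c: labels.at[c, "subject"] for c in cell_ids},
    )


def write_counts(data: LabeledCounts, path, format: str) -> None:
    """Write ``data`` so that :func:`read_counts` inverts it exactly.

    The label table is written next to the matrix as ``<stem>.labels.tsv``.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise DataError(f"unknown format {format!r}; choose from {_FORMATS}")
    path.parent.mkdir(parents=True, exist_ok=True)
    stem = path.with_suffix("")
    if format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(data.counts), precision=17)
        Path(f"{stem}.genes.tsv").write_text("".join(g + "\n" for g in data.gene_ids))
        Path(f"{stem}.cells.tsv").write_text("".join(c + "\n" for c in data.cell_ids))
    else:
        sep = "," if format == "csv" else "\t"
        table = pd.DataFrame(data.counts, index=data.gene_ids, columns=data.cell_ids)
        table.index.name = "gene_id"
        # repr-round-trip float formatting keeps the round trip bit-exact
        table.to_csv(path, sep=sep, float_format="%.17g")
    data.labels_frame().to_csv(f"{stem}.labels.tsv", sep="\t", index=False)


def labels_path_for(path) -> Path:
    """Path of the label sidecar :func:`write_counts` produces for ``path``."""
    return Path(f"{Path(path).with_suffix('')}.labels.tsv")


# ---------------------------------------------------------------------------
# splitting and merging
# ---------------------------------------------------------------------------


def split_train_test(data: LabeledCounts, fraction: float, seed: int) -> SplitResult:
    """Partition cells into train/test halves.

    With two or more subjects, whole subjects are assigned to one half so the
    train-cell fraction comes as close as possible to ``fraction`` (donors are
    never split across halves -- between-subject heterogeneity must separate
    the reference from the pseudo-bulk target).  With a single subject, cells
    are split per cell type (stratified).  Deterministic given ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise DataError("fraction must lie in (0, 1)")
    if data.n_cells < 2:
        raise DataError("need at least 2 cells to split")
    rng = np.random.default_rng(seed)
    subjects = data.subjects
    subj_arr = data.subject_array

    if len(subjects) >= 2:
        sizes = {s: int((subj_arr == s).sum()) for s in subjects}
        total = data.n_cells
        best: List[tuple] = []
        best_err = np.inf
        max_enum = 18
        if len(subjects) <= max_enum:
            for r in range(1, len(subjects)):
                for combo in itertools.combinations(range(len(subjects)), r):
                    frac = sum(sizes[subjects[i]] for i in combo) / total
                    err = abs(frac - fraction)
                    if err < best_err - 1e-12:
                        best, best_err = [combo], err
                    elif abs(err - best_err) <= 1e-12:
                        best.append(combo)
            train_subjects = {subjects[i] for i in best[int(rng.integers(len(best)))]}
        else:  # greedy randomized for very many subjects
            order = rng.permutation(len(subjects))
            train_subjects, acc = set(), 0
            for i in order:
                s = subjects[i]
                if abs((acc + sizes[s]) / total - fraction) <= abs(acc / total - fraction):
                    train_subjects.add(s)
                    acc += sizes[s]
        train_mask = np.isin(subj_arr, sorted(train_subjects))
    else:
        types = data.cell_type_array
        train_mask = np.zeros(data.n_cells, dtype=bool)
        for t in data.cell_types:
            idx = np.flatnonzero(types == t)
            idx = rng.permutation(idx)
            n_train = int(np.floor(fraction * len(idx) + 0.5))
            train_mask[idx[:n_train]] = True

    if train_mask.all() or not train_mask.any():
        raise DataError("fraction yields an empty train or test half")
    return SplitResult(
        train=data.subset_cells(np.flatnonzero(train_mask)),
        test=data.subset_cells(np.flatnonzero(~train_mask)),
    )


def merge_references(
    reference: LabeledCounts, generated: LabeledCounts, case_label: str
) -> LabeledCounts:
    """Append generated cells to the reference as one new subject.

    The generated cells enter the reference as an independent case labelled
    ``case_label``; their cell identifiers are uniquified against the
    reference if needed.  Gene order must match exactly.
    """
    if reference.gene_ids != generated.gene_ids:
        raise DataError("gene sets differ or are ordered differently; cannot merge")
    if case_label in reference.subjects:
        raise DataError(f"case_label {case_label!r} collides with an existing subject")
    if generated.n_cells == 0:
        return reference

    existing = set(reference.cell_ids)
    new_ids = []
    for c in generated.cell_ids:
        cid = c
        k = 0
        while cid in existing:
            k += 1
            cid = f"{c}.{k}"
        existing.add(cid)
        new_ids.append(cid)

    cell_type = dict(reference.cell_type)
    subject = dict(reference.subject)
    for old, new in zip(generated.cell_ids, new_ids):
        cell_type[new] = generated.cell_type[old]
        subject[new] = case_label
    return LabeledCounts(
        counts=np.concatenate([reference.counts, generated.counts], axis=1),
        gene_ids=list(reference.gene_ids),
        cell_ids=list(reference.cell_ids) + new_ids,
        cell_type=cell_type,
        subject=subject,
        normalized=reference.normalized,
    )
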