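"""Readers and writers for association tables, labeled matrices, and ranked predictions.

All on-disk formats are plain TSV (UTF-8). Lines starting with ``#`` and
blank lines are skipped everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationDataset",
    "LabeledMatrix",
    "read_association_table",
    "read_matrix",
    "write_association_table",
    "write_matrix",
    "write_ranked_predictions",
]


@dataclass
class AssociationDataset:
    """A binary bipartite association matrix with ordered entity labels.

    ``Y[i, j] == 1`` means microbe ``microbe_labels[i]`` is associated with
    disease ``disease_labels[j]``.
    """

    microbe_labels: list[str]
    disease_labels: list[str]
    Y: np.ndarray
    n_duplicates: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        n, m = self.Y.shape
        if len(self.microbe_labels) != n or len(self.disease_labels) != m:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.microbe_labels)) != n:
            raise ValueError("duplicate microbe labels")
        if len(set(self.disease_labels)) != m:
            raise ValueError("duplicate disease labels")
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("association matrix must be binary")
        if self.Y.sum() == 0:
            raise ValueError("association matrix has no known associations")

    @property
    def n_microbes(self) -> int:
        return self.Y.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.Y.shape[1]

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Known associations as (microbe index, disease index) pairs."""
        return [tuple(p) for p in np.argwhere(self.Y == 1)]


@dataclass
class LabeledMatrix:
    """A real matrix with row labels (and column labels for rectangular data)."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match matrix shape")

    @property
    def is_square(self) -> bool:
        return self.values.shape[0] == self.values.shape[1]

    def validate_similarity(self, tol: float = 1e-10) -> "LabeledMatrix":
        """Assert the similarity-matrix contract: square, symmetric, nonnegative."""
        if not self.is_square or self.row_labels != self.col_labels:
            raise ValueError("similarity matrix must be square with matching labels")
        if not np.allclose(self.values, self.values.T, atol=tol):
            raise ValueError("similarity matrix is not symmetric")
        if (self.values < 0).any():
            raise ValueError("similarity matrix has negative entries")
        return self

    @property
    def labels(self) -> list[str]:
        if not self.is_square:
            raise ValueError("rectangular matrix has distinct row/column labels")
        return self.row_labels


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    """Non-comment, non-blank lines with their 1-based line numbers."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line))
    return out


def read_association_table(path: str | Path, dedup: bool = True) -> AssociationDataset:
    """Read a 2+-column TSV of (microbe, disease) pairs into a binary matrix.

    Labels are ordered by first appearance; extra columns are ignored. With
    ``dedup`` on, repeated pairs collapse to a single entry and the number of
    dropped duplicates is logged and stored on the returned dataset.
    """
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty association table")

    microbes: dict[str, int] = {}
    diseases: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    n_dup = 0
    for lineno, line in lines:
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"{path}: malformed row at line {lineno} (need >=2 fields)")
        i = microbes.setdefault(fields[0], len(microbes))
        j = diseases.setdefault(fields[1], len(diseases))
        if (i, j) in seen:
            n_dup += 1
            continue
        seen.add((i, j))
        pairs.append((i, j))

    if n_dup and dedup:
        logger.info("dropped %d duplicate association pairs", n_dup)

    Y = np.zeros((len(microbes), len(diseases)))
    for i, j in pairs:
        Y[i, j] = 1.0
    return AssociationDataset(
        microbe_labels=list(microbes),
        disease_labels=list(diseases),
        Y=Y,
        n_duplicates=n_dup if dedup else 0,
    )


def read_matrix(path: str | Path, similarity: bool = False) -> LabeledMatrix:
    """Read a labeled numeric TSV (header row of column labels, first column of
    row labels). With ``similarity=True``, the similarity contract is validated.
    """
    lines = _data_lines(path)
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header row and at least one data row")

    header = lines[0][1].split("\t")
    col_labels = [c.strip() for c in header[1:]]
    if len(set(col_labels)) != len(col_labels):
        raise ValueError(f"{path}: duplicated column labels")

    row_labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(col_labels) + 1:
            raise ValueError(f"{path}: wrong field count at line {lineno}")
        row_labels.append(fields[0].strip())
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell at line {lineno}: {exc}") from exc
    if len(set(row_labels)) != len(row_labels):
        raise ValueError(f"{path}: duplicated row labels")

    mat = LabeledMatrix(row_labels, col_labels, np.array(rows))
    if similarity:
        mat.validate_similarity()
    return mat


def write_association_table(dataset: AssociationDataset, path: str | Path) -> None:
    """Write known pairs back out as a 2-column TSV (inverse of the reader)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in dataset.positive_pairs():
            fh.write(f"{dataset.microbe_labels[i]}\t{dataset.disease_labels[j]}\n")


def write_matrix(mat: LabeledMatrix, path: str | Path, fmt: str = "%.12g") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["."] + list(mat.col_labels)) + "\n")
        for label, row in zip(mat.row_labels, mat.values):
            fh.write("\t".join([label] + [fmt % v for v in row]) + "\n")


def write_ranked_predictions(
    scores: np.ndarray,
    dataset: AssociationDataset,
    path: str | Path,
    mask_known: bool = True,
) -> int:
    """Write (microbe, disease, score, rank) sorted by score descending.

    Ties are broken by (microbe index, disease index) ascending so output is
    reproducible. With ``mask_known``, known positive pairs are excluded.
    Returns the number of rows written.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != dataset.Y.shape:
        raise ValueError(
            f"score shape {scores.shape} does not match associations {dataset.Y.shape}"
        )
    n, m = scores.shape
    entries = [
        (-scores[i, j], i, j)
        for i in range(n)
        for j in range(m)
        if not (mask_known and dataset.Y[i, j] == 1)
    ]
    entries.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#microbe\tdisease\tscore\trank\n")
        for rank, (neg, i, j) in enumerate(entries, start=1):
            fh.write(
                f"{dataset.microbe_labels[i]}\t{dataset.disease_labels[j]}"
                f"\t{-neg:.12g}\t{rank}\n"
            )
    return len(entries)
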