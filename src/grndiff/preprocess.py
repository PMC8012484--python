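"""Expression-matrix containers, normalization and feature exclusion.

Expression data arrive as a genes x samples matrix of non-negative
intensities.  Before network inference we optionally log-transform
(a monotone variance-stabilizing stand-in), quantile-normalize across
samples, and drop excluded features (e.g. probes with unreliable
annotation or on the sex chromosomes — the caller supplies the symbol
list; no chromosome lookup happens here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class PreprocessError(ValueError):
    """Raised when an input violates a preprocessing precondition."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene symbols, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Expression values; must be finite.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise PreprocessError("expression values must be a 2-D matrix")
        if values.shape != (len(genes), len(samples)):
            raise PreprocessError(
                f"shape {values.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if len(set(genes)) != len(genes):
            raise PreprocessError("gene identifiers must be unique")
        if len(set(samples)) != len(samples):
            raise PreprocessError("sample identifiers must be unique")
        if not np.isfinite(values).all():
            raise PreprocessError("expression values contain NaN or infinity")
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(sample_ids)
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise PreprocessError(f"unknown sample id(s): {missing}")
        cols = [index[s] for s in wanted]
        return ExpressionMatrix(self.gene_ids, tuple(wanted), self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            tuple(str(g) for g in frame.index),
            tuple(str(s) for s in frame.columns),
            frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of each sample to one of two responder groups."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "assignments",
            {str(k).strip(): str(v).strip() for k, v in self.assignments.items()},
        )
        if len(set(self.assignments.values())) < 2:
            raise PreprocessError("design must contain at least two non-empty groups")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.assignments.values())))

    def samples_in(self, group: str) -> list[str]:
        return sorted(s for s, g in self.assignments.items() if g == group)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.assignments]
        if missing:
            raise PreprocessError(f"samples without a group label: {missing}")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression table (first column = gene symbol)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.isna().any().any():
        raise PreprocessError(f"{path}: missing values in expression table")
    return ExpressionMatrix.from_frame(frame)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().rename_axis("gene").to_csv(path, sep="\t")


def read_design(path: str | Path) -> GroupDesign:
    """Read a two-column sample annotation table (sample_id, group)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(frame.columns):
        raise PreprocessError(f"{path}: design table needs columns {sorted(required)}")
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise PreprocessError(f"{path}: duplicated sample id(s): {dup}")
    return GroupDesign(dict(zip(frame["sample_id"], frame["group"])))


def write_design(design: GroupDesign, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(design.assignments), "group": list(design.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


def filter_features(matrix: ExpressionMatrix, exclude: Iterable[str]) -> ExpressionMatrix:
    """Drop rows whose gene symbol is in ``exclude``; row order preserved.

    Symbols in ``exclude`` that are absent from the matrix are ignored.
    """
    excluded = {str(g) for g in exclude}
    keep = [i for i, g in enumerate(matrix.gene_ids) if g not in excluded]
    if not keep:
        raise PreprocessError("feature filter would remove every gene")
    return ExpressionMatrix(
        tuple(matrix.gene_ids[i] for i in keep),
        matrix.sample_ids,
        matrix.values[keep, :],
    )


def variance_stabilize(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Monotone log2(x + offset) transform of non-negative intensities.

    Any strictly monotone variance-stabilizing transform could be
    substituted: downstream inference consumes Pearson correlations of
    within-gene profiles, so only the monotone shape matters here.
    """
    if offset <= 0:
        raise PreprocessError("offset must be positive")
    if (matrix.values < 0).any():
        raise PreprocessError("variance_stabilize requires non-negative values")
    return ExpressionMatrix(
        matrix.gene_ids, matrix.sample_ids, np.log2(matrix.values + offset)
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the shared mean order-statistic scale.

    The reference distribution is the across-sample mean of the sorted
    columns; each column's values are replaced by the reference value at
    their rank, ties receiving the mean of the reference values over the
    tied ranks.  Idempotent up to floating-point error.
    """
    if matrix.n_samples < 2:
        raise PreprocessError("quantile normalization needs at least 2 samples")
    values = matrix.values
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average the reference over tied ranks
        uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < len(col):
            sums = np.bincount(inverse, weights=assigned)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, out)
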