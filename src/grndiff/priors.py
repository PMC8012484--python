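"""TF -> target prior maps: parsing and reconciliation with expression data.

The network prior is a curated list of known transcription-factor ->
target-gene interactions (e.g. a TRRUST-style export): a two-column
tab-separated edge list that becomes a 0/1 bipartite TF x gene matrix.
Before inference the prior is intersected with the expression matrix so
that every TF and every target has an expression profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .preprocess import ExpressionMatrix


class PriorParseError(ValueError):
    pass


class PriorSummary(NamedTuple):
    n_tfs: int
    n_pairs: int
    n_genes: int


@dataclass(frozen=True)
class PriorMap:
    """Bipartite 0/1 prior: rows are TFs, columns are target genes."""

    tf_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    W0: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        tfs = tuple(str(t) for t in self.tf_ids)
        genes = tuple(str(g) for g in self.gene_ids)
        W0 = np.asarray(self.W0, dtype=float)
        if W0.shape != (len(tfs), len(genes)):
            raise PriorParseError("prior matrix shape does not match identifier lists")
        if not np.isin(W0, (0.0, 1.0)).all():
            raise PriorParseError("prior entries must be 0 or 1")
        if len(set(tfs)) != len(tfs) or len(set(genes)) != len(genes):
            raise PriorParseError("TF and gene identifiers must be unique")
        if (W0.sum(axis=1) == 0).any():
            empty = [t for t, s in zip(tfs, W0.sum(axis=1)) if s == 0]
            raise PriorParseError(f"TF(s) with no targets: {empty}")
        object.__setattr__(self, "tf_ids", tfs)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "W0", W0)

    @property
    def summary(self) -> PriorSummary:
        return PriorSummary(len(self.tf_ids), int(self.W0.sum()), len(self.gene_ids))

    @classmethod
    def from_pairs(cls, pairs: set[tuple[str, str]]) -> "PriorMap":
        if not pairs:
            raise PriorParseError("empty prior")
        tfs = tuple(sorted({t for t, _ in pairs}))
        genes = tuple(sorted({g for _, g in pairs}))
        tf_index = {t: i for i, t in enumerate(tfs)}
        gene_index = {g: j for j, g in enumerate(genes)}
        W0 = np.zeros((len(tfs), len(genes)))
        for t, g in pairs:
            W0[tf_index[t], gene_index[g]] = 1.0
        return cls(tfs, genes, W0)

    def pairs(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.W0)
        return {(self.tf_ids[i], self.gene_ids[j]) for i, j in zip(rows, cols)}


def read_prior(path: str | Path) -> PriorMap:
    """Parse a two-column (tf, target) tab-separated edge list.

    An optional header line is recognised when its first field is the
    literal ``tf`` (any case).  Duplicate pairs are collapsed; symbols
    are whitespace-trimmed and compared case-sensitively.
    """
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) != 2:
                raise PriorParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            if lineno == 1 and fields[0].lower() == "tf":
                continue
            if not fields[0] or not fields[1]:
                raise PriorParseError(f"{path}:{lineno}: empty symbol")
            pairs.add((fields[0], fields[1]))
    if not pairs:
        raise PriorParseError(f"{path}: no interactions found")
    return PriorMap.from_pairs(pairs)


def write_prior(prior: PriorMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("tf\ttarget\n")
        for t, g in sorted(prior.pairs()):
            handle.write(f"{t}\t{g}\n")


def intersect_prior(
    prior: PriorMap, matrix: ExpressionMatrix
) -> tuple[PriorMap, PriorSummary]:
    """Restrict the prior to TFs and targets measured in the expression matrix.

    TFs must themselves appear as expression rows (their profiles drive
    the co-operativity messages); TFs left without any measured target
    are dropped.  Returns the reconciled prior and its summary counts.
    """
    measured = set(matrix.gene_ids)
    kept = {
        (t, g)
        for t, g in prior.pairs()
        if t in measured and g in measured
    }
    if not kept:
        raise PriorParseError("prior and expression matrix share no usable interactions")
    reconciled = PriorMap.from_pairs(kept)
    return reconciled, reconciled.summary
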