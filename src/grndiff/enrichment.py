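"""Local over-representation analysis (ORA) of TF-centred gene sets.

For each top TF and subnetwork, the query set is the TF itself plus
the genes it is differentially connected to.  Each annotated gene set
is tested with the upper-tail hypergeometric probability of observing
at least the realised overlap, against a background of the genes the
analysis could have connected (all genes in the preprocessed
expression matrix).  p-values are Benjamini–Hochberg adjusted within
each query's batch of tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .differential import DifferentialSubnetwork

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: name -> (description, member symbols)."""

    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise EnrichmentError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes...

    Duplicate member symbols within a set are collapsed; a line with
    fewer than three fields is a parse error.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 3:
                raise EnrichmentError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise EnrichmentError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise EnrichmentError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = (description, members)
    if not sets:
        raise EnrichmentError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    query_n: int
    set_n: int
    background_n: int
    p: float
    p_adj: float


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a query against every set.

    Raw p is the probability of drawing at least the observed overlap
    when sampling |query| genes from the background; adjusted p is
    Benjamini–Hochberg across all sets tested for this query.  Results
    are sorted by raw p, then set name.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise EnrichmentError("empty query")
    if not background:
        raise EnrichmentError("empty background")
    stray = query - background
    if stray:
        raise EnrichmentError(f"query genes outside the background: {sorted(stray)[:5]}")

    M = len(background)
    n = len(query)
    names, raw = [], []
    meta = {}
    for name in sorted(collection.sets):
        members = collection.members(name) & background
        k = len(members & query)
        K = len(members)
        # P(X >= k) for X ~ Hypergeom(M, K, n)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        names.append(name)
        raw.append(min(p, 1.0))
        meta[name] = (k, K)
    adjusted = multipletests(raw, method="fdr_bh")[1] if names else []
    results = [
        EnrichmentResult(
            set_name=name,
            overlap=meta[name][0],
            query_n=n,
            set_n=meta[name][1],
            background_n=M,
            p=p,
            p_adj=float(max(pa, p)),
        )
        for name, p, pa in zip(names, raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap": r.overlap,
                "query_n": r.query_n,
                "set_n": r.set_n,
                "bg_n": r.background_n,
                "p": r.p,
                "p_adj": r.p_adj,
            }
            for r in results
        ],
        columns=["set_name", "overlap", "query_n", "set_n", "bg_n", "p", "p_adj"],
    )


def run_enrichment(
    subnet_g: DifferentialSubnetwork,
    subnet_p: DifferentialSubnetwork,
    collection: GeneSetCollection,
    background: Iterable[str],
    tfs: Iterable[str] | None = None,
) -> dict[tuple[str, str], list[EnrichmentResult]]:
    """Per-TF, per-subnetwork ORA of {TF} + its differentially connected genes.

    A TF with no connected genes in a subnetwork is skipped (logged),
    mirroring the empty cells of a per-TF enrichment report.  BH
    adjustment is scoped within each (TF, subnetwork) query.
    """
    background = set(background)
    tables: dict[tuple[str, str], list[EnrichmentResult]] = {}
    for subnet in (subnet_g, subnet_p):
        queried = tfs if tfs is not None else subnet.tfs
        for tf in queried:
            genes = subnet.genes_of(tf)
            if not genes:
                logger.info("TF %s has no connected genes in %s subnetwork; skipped",
                            tf, subnet.group)
                continue
            query = ({tf} | set(genes)) & background
            if not query:
                logger.info("TF %s query entirely outside background; skipped", tf)
                continue
            tables[(subnet.group, tf)] = ora(query, collection, background)
    return tables


def significant(
    tables: Mapping[tuple[str, str], list[EnrichmentResult]], alpha: float = 0.001
) -> pd.DataFrame:
    """Flatten per-query tables, keeping rows with adjusted p below alpha."""
    rows = []
    for (group, tf), results in sorted(tables.items()):
        for r in results:
            if r.p_adj < alpha:
                rows.append({"group": group, "tf": tf, **results_frame([r]).iloc[0]})
    return pd.DataFrame(
        rows,
        columns=["group", "tf", "set_name", "overlap", "query_n", "set_n", "bg_n",
                 "p", "p_adj"],
    )
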