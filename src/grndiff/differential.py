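"""Differential connectivity between two aggregate networks.

The contrast between the good-responder (GR) and poor-responder (PR)
aggregates is summarised per TF by the edge enrichment score

    EES_i = log2[ (k_g_i / k_p_i) / (N_g / N_p) ],

where k_g_i and k_p_i are TF i's high-confidence out-degrees in the GR
and PR aggregates and N_g, N_p the total high-confidence edge counts.
A positive score means TF i's edges are over-represented in the GR
network, a negative one in the PR network.  The most extreme TFs
(default 5 highest + 5 lowest) seed two differential subnetworks: an
edge joins the GR subnetwork when its mean-Z difference
dZ = meanZ_GR - meanZ_PR exceeds a threshold (default 0.75) and the
edge is high-confidence in the GR aggregate, and symmetrically for PR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .resample import AggregateNetwork

logger = logging.getLogger(__name__)


class DifferentialError(ValueError):
    pass


class UndefinedScoreError(DifferentialError):
    """The EES is undefined when any count in the log-ratio is zero."""


def edge_enrichment_score(k_g: int, k_p: int, N_g: int, N_p: int) -> float:
    """Evaluate EES = log2[(k_g/k_p)/(N_g/N_p)].

    All four counts must be positive; a zero anywhere makes the
    log-ratio undefined and raises :class:`UndefinedScoreError`.
    """
    if min(k_g, k_p, N_g, N_p) <= 0:
        raise UndefinedScoreError(
            f"EES undefined for counts k_g={k_g}, k_p={k_p}, N_g={N_g}, N_p={N_p}"
        )
    return math.log2((k_g / k_p) / (N_g / N_p))


@dataclass(frozen=True)
class EesRecord:
    tf: str
    k_g: int
    k_p: int
    ees: float | None  # None when the score is undefined (a zero count)

    @property
    def n_diff(self) -> int:
        return self.k_g - self.k_p

    @property
    def defined(self) -> bool:
        return self.ees is not None


@dataclass(frozen=True)
class EesTable:
    """Per-TF edge-enrichment records, defined ones sorted by EES descending."""

    records: tuple[EesRecord, ...]
    undefined: tuple[EesRecord, ...]
    N_g: int
    N_p: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tf": r.tf,
                "k_g": r.k_g,
                "k_p": r.k_p,
                "n_diff": r.n_diff,
                "log2_ees": r.ees if r.defined else float("nan"),
            }
            for r in self.records + self.undefined
        ]
        return pd.DataFrame(rows, columns=["tf", "k_g", "k_p", "n_diff", "log2_ees"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, tuple[int, int]], N_g: int, N_p: int
    ) -> "EesTable":
        """Build a table directly from per-TF (k_g, k_p) out-degree counts."""
        defined, undefined = [], []
        for tf, (k_g, k_p) in counts.items():
            try:
                score = edge_enrichment_score(k_g, k_p, N_g, N_p)
                defined.append(EesRecord(tf, k_g, k_p, score))
            except UndefinedScoreError:
                logger.info("TF %s excluded from EES ranking (zero count)", tf)
                undefined.append(EesRecord(tf, k_g, k_p, None))
        defined.sort(key=lambda r: (-r.ees, r.tf))
        undefined.sort(key=lambda r: r.tf)
        return cls(tuple(defined), tuple(undefined), N_g, N_p)


def ees_table(agg_g: AggregateNetwork, agg_p: AggregateNetwork) -> EesTable:
    """Per-TF EES from two aggregates sharing TF/gene ordering."""
    if agg_g.tf_ids != agg_p.tf_ids or agg_g.gene_ids != agg_p.gene_ids:
        raise DifferentialError("aggregates disagree on TF/gene identifiers or order")
    k_g = agg_g.hc_mask.sum(axis=1)
    k_p = agg_p.hc_mask.sum(axis=1)
    counts = {
        tf: (int(kg), int(kp)) for tf, kg, kp in zip(agg_g.tf_ids, k_g, k_p)
    }
    return EesTable.from_counts(counts, agg_g.n_edges, agg_p.n_edges)


def select_top_tfs(table: EesTable, n_high: int = 5, n_low: int = 5) -> list[str]:
    """The n_high highest- and n_low lowest-EES TFs (ties broken by symbol).

    Only TFs with a defined score participate.  Returns the high block
    (EES descending) followed by the low block (EES ascending).
    """
    defined = list(table.records)
    if len(defined) < n_high + n_low:
        raise DifferentialError(
            f"need at least {n_high + n_low} defined records, have {len(defined)}"
        )
    high = sorted(defined, key=lambda r: (-r.ees, r.tf))[:n_high]
    low = sorted(defined, key=lambda r: (r.ees, r.tf))[:n_low]
    return [r.tf for r in high] + [r.tf for r in low]


@dataclass(frozen=True)
class DifferentialSubnetwork:
    """Directed TF -> gene edges assigned to one group, with per-edge dZ."""

    group: str
    edges: tuple[tuple[str, str, float], ...]  # (tf, gene, delta_z)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.edges, key=lambda e: (e[0], e[1])))
        object.__setattr__(self, "edges", ordered)

    @property
    def tfs(self) -> tuple[str, ...]:
        return tuple(sorted({t for t, _, _ in self.edges}))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({g for _, g, _ in self.edges}))

    def genes_of(self, tf: str) -> list[str]:
        return sorted(g for t, g, _ in self.edges if t == tf)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["tf", "gene", "delta_z"])

    def to_networkx(self) -> nx.DiGraph:
        graph = nx.DiGraph(group=self.group)
        for tf in self.tfs:
            graph.add_node(tf, role="tf")
        for g in self.genes:
            if g not in graph:
                graph.add_node(g, role="gene")
        for tf, g, dz in self.edges:
            graph.add_edge(tf, g, delta_z=dz)
        return graph


def differential_edges(
    agg_g: AggregateNetwork,
    agg_p: AggregateNetwork,
    tfs: Sequence[str],
    delta: float = 0.75,
    mode: Literal["signed", "absolute"] = "signed",
    hc_side: Literal["assigned", "other"] = "assigned",
) -> tuple[DifferentialSubnetwork, DifferentialSubnetwork]:
    """Split the selected TFs' differential edges into GR and PR subnetworks.

    For each selected TF and each gene, dZ = meanZ_GR - meanZ_PR.  In
    the default ``signed`` mode an edge joins the GR subnetwork when
    dZ > delta, the PR subnetwork when -dZ > delta; ``absolute`` mode
    instead requires |dZ| > delta and assigns by high-confidence
    membership, which can place an edge in both subnetworks.  The
    high-confidence requirement is checked on the subnetwork the edge
    is assigned to (``hc_side='assigned'``) or on the opposite one.
    """
    if agg_g.tf_ids != agg_p.tf_ids or agg_g.gene_ids != agg_p.gene_ids:
        raise DifferentialError("aggregates disagree on TF/gene identifiers or order")
    if delta < 0:
        raise DifferentialError("delta must be non-negative")
    tf_index = {t: i for i, t in enumerate(agg_g.tf_ids)}
    unknown = [t for t in tfs if t not in tf_index]
    if unknown:
        raise DifferentialError(f"unknown TF(s): {unknown}")

    dz = agg_g.mean_z - agg_p.mean_z
    hc_g, hc_p = agg_g.hc_mask, agg_p.hc_mask
    edges_g: list[tuple[str, str, float]] = []
    edges_p: list[tuple[str, str, float]] = []
    for tf in tfs:
        i = tf_index[tf]
        for j, gene in enumerate(agg_g.gene_ids):
            d = float(dz[i, j])
            if mode == "signed":
                to_g = d > delta
                to_p = -d > delta
            elif mode == "absolute":
                to_g = to_p = abs(d) > delta
            else:
                raise DifferentialError(f"unknown mode {mode!r}")
            hc_for_g = hc_g[i, j] if hc_side == "assigned" else hc_p[i, j]
            hc_for_p = hc_p[i, j] if hc_side == "assigned" else hc_g[i, j]
            if hc_side not in ("assigned", "other"):
                raise DifferentialError(f"unknown hc_side {hc_side!r}")
            if to_g and hc_for_g:
                edges_g.append((tf, gene, d))
            if to_p and hc_for_p:
                edges_p.append((tf, gene, d))
    return (
        DifferentialSubnetwork("GR", tuple(edges_g)),
        DifferentialSubnetwork("PR", tuple(edges_p)),
    )


def export_subnetwork(
    net: DifferentialSubnetwork, path: str | Path, fmt: str = "tsv"
) -> None:
    """Write a subnetwork as a long TSV (tf, gene, delta_z) or SIF file."""
    path = Path(path)
    if fmt == "tsv":
        net.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as handle:
            for tf, gene, _ in net.edges:
                handle.write(f"{tf}\tregulates\t{gene}\n")
    else:
        raise DifferentialError(f"unknown subnetwork format {fmt!r}")


def read_subnetwork(path: str | Path, group: str) -> DifferentialSubnetwork:
    frame = pd.read_csv(path, sep="\t")
    edges = tuple(
        (str(r.tf), str(r.gene), float(r.delta_z)) for r in frame.itertuples()
    )
    return DifferentialSubnetwork(group, edges)
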