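"""Subsample-and-aggregate network estimation.

With small cohorts a single inferred network is dominated by
individual outliers.  The remedy used here: repeatedly draw a fixed
fraction (default two-thirds) of each group's samples without
replacement, infer a network per draw, and average the edge Z-scores
across draws into one aggregate network per group.  Edges whose mean
Z-score exceeds a threshold (default 0) are flagged high-confidence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panda import RegulatoryNetwork
from .preprocess import GroupDesign


class ResampleError(ValueError):
    pass


@dataclass(frozen=True)
class SubsamplePlan:
    """One replicate's sample draw, reproducible from (seed, group, index)."""

    group: str
    index: int
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ResampleError("subsample contains repeated samples")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))


@dataclass(frozen=True)
class AggregateNetwork:
    """Edge-wise mean of replicate networks plus its high-confidence mask."""

    tf_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    mean_z: np.ndarray = field(repr=False)
    n_reps: int = 1
    hc_threshold: float = 0.0

    def __post_init__(self) -> None:
        mean_z = np.asarray(self.mean_z, dtype=float)
        if mean_z.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ResampleError("mean_z shape does not match identifier lists")
        object.__setattr__(self, "tf_ids", tuple(self.tf_ids))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "mean_z", mean_z)

    @property
    def hc_mask(self) -> np.ndarray:
        """Boolean mask of high-confidence edges: mean Z strictly above threshold."""
        return self.mean_z > self.hc_threshold

    @property
    def n_edges(self) -> int:
        """Total number of high-confidence edges in the aggregate."""
        return int(self.hc_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.mean_z, index=list(self.tf_ids), columns=list(self.gene_ids)
        )
        return frame

    def to_long(self) -> pd.DataFrame:
        long = (
            self.to_frame()
            .rename_axis("tf")
            .reset_index()
            .melt(id_vars="tf", var_name="gene", value_name="mean_z")
        )
        long["high_confidence"] = (long["mean_z"] > self.hc_threshold).astype(int)
        return long.sort_values(["tf", "gene"], kind="stable").reset_index(drop=True)


def _group_rng(seed: int, group: str) -> np.random.Generator:
    # independent substream per group label
    return np.random.default_rng([int(seed), zlib.crc32(group.encode("utf-8"))])


def draw_subsamples(
    design: GroupDesign,
    group: str,
    fraction: float = 2 / 3,
    n_reps: int = 50,
    seed: int = 0,
) -> list[SubsamplePlan]:
    """Draw ``n_reps`` without-replacement subsamples of one group.

    Each replicate takes ceil(fraction * group size) distinct samples.
    The draws are fully determined by (seed, group): the same seed
    reproduces the same plans.
    """
    if not 0 < fraction <= 1:
        raise ResampleError("fraction must be in (0, 1]")
    members = design.samples_in(group)
    if len(members) < 3:
        raise ResampleError(f"group {group!r} has fewer than 3 samples")
    size = ceil(fraction * len(members))
    if size < 3:
        raise ResampleError(
            f"subsample size {size} is too small to estimate correlations"
        )
    rng = _group_rng(seed, group)
    plans = []
    for index in range(1, n_reps + 1):
        chosen = rng.choice(len(members), size=size, replace=False)
        ids = tuple(sorted(members[i] for i in chosen))
        plans.append(SubsamplePlan(group=group, index=index, sample_ids=ids))
    return plans


def write_plan_manifest(plans: Sequence[SubsamplePlan], path: str | Path) -> None:
    pd.DataFrame(
        {
            "group": [p.group for p in plans],
            "replicate": [p.index for p in plans],
            "sample_ids": [",".join(p.sample_ids) for p in plans],
        }
    ).to_csv(path, sep="\t", index=False)


def write_aggregate(agg: AggregateNetwork, path: str | Path) -> None:
    agg.to_long().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_aggregate(path: str | Path, hc_threshold: float = 0.0) -> AggregateNetwork:
    """Rebuild an aggregate from its long-format TSV export."""
    long = pd.read_csv(path, sep="\t", dtype={"tf": str, "gene": str})
    wide = long.pivot(index="tf", columns="gene", values="mean_z").sort_index()
    wide = wide[sorted(wide.columns)]
    return AggregateNetwork(
        tuple(wide.index),
        tuple(wide.columns),
        wide.to_numpy(dtype=float),
        hc_threshold=hc_threshold,
    )


def aggregate(
    networks: Sequence[RegulatoryNetwork], hc_threshold: float = 0.0
) -> AggregateNetwork:
    """Edge-wise mean of replicate networks; order of the list is irrelevant."""
    if not networks:
        raise ResampleError("aggregate needs at least one network")
    first = networks[0]
    for net in networks[1:]:
        if net.tf_ids != first.tf_ids or net.gene_ids != first.gene_ids:
            raise ResampleError("networks disagree on TF/gene identifiers or order")
    mean_z = np.mean([net.Z for net in networks], axis=0)
    return AggregateNetwork(
        first.tf_ids,
        first.gene_ids,
        mean_z,
        n_reps=len(networks),
        hc_threshold=hc_threshold,
    )
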