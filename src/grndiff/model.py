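"""Model/results interface tying the pipeline stages together.

:class:`DifferentialNetworkModel` holds the data (expression matrix,
two-group design, TF->target prior) and the analysis configuration;
:meth:`~DifferentialNetworkModel.fit` runs preprocessing, per-group
subsample network inference, aggregation, edge-enrichment scoring and
differential-subnetwork extraction, returning a
:class:`DifferentialNetworkResults` with the estimates, diagnostics
and exporters.  Gene-set over-representation hangs off the results
object because it needs only the fitted subnetworks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .differential import (
    DifferentialSubnetwork,
    EesTable,
    differential_edges,
    ees_table,
    export_subnetwork,
    select_top_tfs,
)
from .enrichment import (
    EnrichmentResult,
    GeneSetCollection,
    results_frame,
    run_enrichment,
    significant,
)
from .panda import PandaConfig, RegulatoryNetwork, infer_network
from .preprocess import (
    ExpressionMatrix,
    GroupDesign,
    filter_features,
    quantile_normalize,
    read_design,
    read_expression,
    variance_stabilize,
)
from .priors import PriorMap, PriorSummary, intersect_prior, read_prior
from .resample import (
    AggregateNetwork,
    SubsamplePlan,
    aggregate,
    draw_subsamples,
    write_aggregate,
    write_plan_manifest,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis constants; the defaults are the study's stated settings.

    n_reps : 50 subsample networks per group.
    fraction : two-thirds of each group drawn without replacement.
    hc_threshold : high-confidence edges have mean Z strictly above 0.
    delta : differential edges have |dZ| above 0.75.
    n_high / n_low : 5 highest + 5 lowest EES TFs are selected.
    enrichment_alpha : adjusted-p cutoff 0.001 for the significant report.
    apply_vst : log-transform raw non-negative intensities before
        quantile normalization (off for data already on a linear scale).
    """

    n_reps: int = 50
    fraction: float = 2 / 3
    hc_threshold: float = 0.0
    delta: float = 0.75
    n_high: int = 5
    n_low: int = 5
    enrichment_alpha: float = 0.001
    panda: PandaConfig = field(default_factory=PandaConfig)
    seed: int = 0
    apply_vst: bool = False
    vst_offset: float = 1.0
    exclude_genes: tuple[str, ...] = ()
    group_good: str = "GR"
    group_poor: str = "PR"
    diff_mode: str = "signed"
    hc_side: str = "assigned"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclude_genes"] = list(self.exclude_genes)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        if "panda" in data and isinstance(data["panda"], Mapping):
            data["panda"] = PandaConfig(**data["panda"])
        if "exclude_genes" in data:
            data["exclude_genes"] = tuple(data["exclude_genes"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


@dataclass
class DifferentialNetworkResults:
    """Fitted estimates of one differential-network analysis."""

    model: "DifferentialNetworkModel"
    config: PipelineConfig
    seed: int
    matrix: ExpressionMatrix
    prior: PriorMap
    prior_summary: PriorSummary
    plans: dict[str, list[SubsamplePlan]]
    agg_good: AggregateNetwork
    agg_poor: AggregateNetwork
    replicate_checksums: pd.DataFrame
    n_converged: int
    n_runs: int
    ees: EesTable
    top_tfs: list[str]
    subnet_good: DifferentialSubnetwork
    subnet_poor: DifferentialSubnetwork
    enrichment_tables: dict[tuple[str, str], list[EnrichmentResult]] | None = None

    def summary(self) -> str:
        """Human-readable account of the fit, Table-2-style at the bottom."""
        cfg = self.config
        lines = [
            "Differential regulatory network analysis",
            "=" * 56,
            f"groups: {cfg.group_good} (n={len(self.model.design.samples_in(cfg.group_good))})"
            f" vs {cfg.group_poor} (n={len(self.model.design.samples_in(cfg.group_poor))})",
            f"prior: {self.prior_summary.n_tfs} TFs, {self.prior_summary.n_pairs} "
            f"interactions, {self.prior_summary.n_genes} target genes",
            f"subsamples: {cfg.n_reps} per group at fraction {cfg.fraction:.4g}, seed {self.seed}",
            f"converged message-passing runs: {self.n_converged}/{self.n_runs}",
            f"high-confidence edges (mean Z > {cfg.hc_threshold:g}): "
            f"N_g={self.agg_good.n_edges}, N_p={self.agg_poor.n_edges}",
            "",
            f"top {cfg.n_high}+{cfg.n_low} TFs by edge enrichment score:",
            f"{'tf':<12}{'k_g':>8}{'k_p':>8}{'n_diff':>8}{'log2_ees':>10}",
        ]
        by_tf = {r.tf: r for r in self.ees.records}
        for tf in self.top_tfs:
            r = by_tf[tf]
            lines.append(
                f"{r.tf:<12}{r.k_g:>8}{r.k_p:>8}{r.n_diff:>8}{r.ees:>10.3f}"
            )
        lines.append("")
        lines.append(
            f"differential edges (|dZ| > {cfg.delta:g}): "
            f"{cfg.group_good} subnetwork {len(self.subnet_good.edges)}, "
            f"{cfg.group_poor} subnetwork {len(self.subnet_poor.edges)}"
        )
        return "\n".join(lines)

    def run_enrichment(
        self,
        collection: GeneSetCollection,
        background: Iterable[str] | None = None,
    ) -> dict[tuple[str, str], list[EnrichmentResult]]:
        """ORA of each top TF + its differential targets; background
        defaults to all genes of the preprocessed expression matrix."""
        bg = set(background) if background is not None else set(self.matrix.gene_ids)
        self.enrichment_tables = run_enrichment(
            self.subnet_good, self.subnet_poor, collection, bg, tfs=self.top_tfs
        )
        return self.enrichment_tables

    def save(self, outdir: str | Path) -> Path:
        """Write every intermediate and final artifact to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(
            json.dumps({"seed": self.seed, **self.config.to_dict()}, indent=1)
        )
        write_plan_manifest(
            self.plans[self.config.group_good] + self.plans[self.config.group_poor],
            outdir / "plans.tsv",
        )
        self.replicate_checksums.to_csv(
            outdir / "replicate_checksums.tsv", sep="\t", index=False
        )
        write_aggregate(self.agg_good, outdir / f"aggregate_{self.config.group_good}.tsv")
        write_aggregate(self.agg_poor, outdir / f"aggregate_{self.config.group_poor}.tsv")
        self.ees.write(outdir / "ees.tsv")
        (outdir / "top_tfs.txt").write_text("\n".join(self.top_tfs) + "\n")
        for subnet, label in (
            (self.subnet_good, self.config.group_good),
            (self.subnet_poor, self.config.group_poor),
        ):
            export_subnetwork(subnet, outdir / f"subnetwork_{label}.tsv", "tsv")
            export_subnetwork(subnet, outdir / f"subnetwork_{label}.sif", "sif")
        if self.enrichment_tables is not None:
            rows = []
            for (group, tf), results in sorted(self.enrichment_tables.items()):
                frame = results_frame(results)
                frame.insert(0, "tf", tf)
                frame.insert(0, "group", group)
                rows.append(frame)
            full = (
                pd.concat(rows, ignore_index=True)
                if rows
                else results_frame([]).assign(group=[], tf=[])
            )
            full.to_csv(outdir / "enrichment_full.tsv", sep="\t", index=False)
            significant(
                self.enrichment_tables, self.config.enrichment_alpha
            ).to_csv(outdir / "enrichment_significant.tsv", sep="\t", index=False)
        (outdir / "run.log").write_text(self.summary() + "\n")
        return outdir


class DifferentialNetworkModel:
    """Two-group differential regulatory-network model.

    Parameters
    ----------
    expression : ExpressionMatrix
        Raw genes x samples expression values.
    design : GroupDesign
        Sample -> group assignment covering every sample.
    prior : PriorMap
        TF -> target prior (need not be pre-intersected).
    config : PipelineConfig, optional
        Analysis constants; defaults are the study settings.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        design: GroupDesign,
        prior: PriorMap,
        config: PipelineConfig | None = None,
    ):
        self.expression = expression
        self.design = design
        self.prior = prior
        self.config = config or PipelineConfig()
        design.validate_against(expression)
        for group in (self.config.group_good, self.config.group_poor):
            if not design.samples_in(group):
                raise PipelineError(
                    "design", ValueError(f"group {group!r} has no samples")
                )

    @classmethod
    def from_files(
        cls,
        expression: str | Path,
        design: str | Path,
        prior: str | Path,
        config: PipelineConfig | None = None,
    ) -> "DifferentialNetworkModel":
        return cls(
            read_expression(expression),
            read_design(design),
            read_prior(prior),
            config,
        )

    # -- fitting ---------------------------------------------------------

    def _preprocess(self) -> ExpressionMatrix:
        matrix = self.expression
        if self.config.exclude_genes:
            matrix = filter_features(matrix, self.config.exclude_genes)
        if self.config.apply_vst:
            matrix = variance_stabilize(matrix, self.config.vst_offset)
        return quantile_normalize(matrix)

    def _replicate_network(
        self,
        matrix: ExpressionMatrix,
        prior: PriorMap,
        plan: SubsamplePlan,
        cache_dir: Path | None,
    ) -> RegulatoryNetwork:
        key = None
        if cache_dir is not None:
            payload = json.dumps(
                {
                    "panda": asdict(self.config.panda),
                    "group": plan.group,
                    "replicate": plan.index,
                    "samples": plan.sample_ids,
                    "matrix": hashlib.sha256(matrix.values.tobytes()).hexdigest(),
                    "prior": sorted(prior.pairs()),
                },
                sort_keys=True,
            )
            key = hashlib.sha256(payload.encode()).hexdigest()[:24]
            cached = cache_dir / f"{key}.npy"
            if cached.exists():
                Z = np.load(cached)
                return RegulatoryNetwork(prior.tf_ids, prior.gene_ids, Z)
        net = infer_network(
            matrix.subset_samples(plan.sample_ids), prior, cfg=self.config.panda
        )
        if cache_dir is not None and key is not None:
            cache_dir.mkdir(parents=True, exist_ok=True)
            np.save(cache_dir / f"{key}.npy", net.Z)
        return net

    def fit(
        self, seed: int | None = None, cache_dir: str | Path | None = None
    ) -> DifferentialNetworkResults:
        """Run the full analysis; fully deterministic given the seed."""
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        cache = Path(cache_dir) if cache_dir is not None else None

        try:
            matrix = self._preprocess()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError("preprocess", exc) from exc
        try:
            prior, prior_summary = intersect_prior(self.prior, matrix)
        except Exception as exc:
            raise PipelineError("prior_intersection", exc) from exc

        plans: dict[str, list[SubsamplePlan]] = {}
        aggregates: dict[str, AggregateNetwork] = {}
        checksum_rows = []
        n_converged = n_runs = 0
        for group in (cfg.group_good, cfg.group_poor):
            try:
                plans[group] = draw_subsamples(
                    self.design, group, cfg.fraction, cfg.n_reps, seed
                )
                nets = []
                for plan in plans[group]:
                    net = self._replicate_network(matrix, prior, plan, cache)
                    nets.append(net)
                    n_runs += 1
                    n_converged += int(net.converged)
                    checksum_rows.append(
                        {
                            "group": group,
                            "replicate": plan.index,
                            "sha256": hashlib.sha256(net.Z.tobytes()).hexdigest(),
                        }
                    )
                aggregates[group] = aggregate(nets, cfg.hc_threshold)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"inference[{group}]", exc) from exc

        agg_good, agg_poor = aggregates[cfg.group_good], aggregates[cfg.group_poor]
        try:
            table = ees_table(agg_good, agg_poor)
            top = select_top_tfs(table, cfg.n_high, cfg.n_low)
            subnet_good, subnet_poor = differential_edges(
                agg_good,
                agg_poor,
                top,
                delta=cfg.delta,
                mode=cfg.diff_mode,  # type: ignore[arg-type]
                hc_side=cfg.hc_side,  # type: ignore[arg-type]
            )
        except Exception as exc:
            raise PipelineError("differential", exc) from exc

        return DifferentialNetworkResults(
            model=self,
            config=cfg,
            seed=seed,
            matrix=matrix,
            prior=prior,
            prior_summary=prior_summary,
            plans=plans,
            agg_good=agg_good,
            agg_poor=agg_poor,
            replicate_checksums=pd.DataFrame(
                checksum_rows, columns=["group", "replicate", "sha256"]
            ),
            n_converged=n_converged,
            n_runs=n_runs,
            ees=table,
            top_tfs=top,
            subnet_good=DifferentialSubnetwork(cfg.group_good, subnet_good.edges),
            subnet_poor=DifferentialSubnetwork(cfg.group_poor, subnet_poor.edges),
        )


def run_pipeline(
    expression: str | Path,
    design: str | Path,
    prior: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    gmt: str | Path | None = None,
    cache_dir: str | Path | None = None,
) -> DifferentialNetworkResults:
    """File-to-file convenience wrapper: read inputs, fit, write artifacts."""
    from .enrichment import read_gmt

    model = DifferentialNetworkModel.from_files(expression, design, prior, config)
    results = model.fit(cache_dir=cache_dir)
    if gmt is not None:
        results.run_enrichment(read_gmt(gmt))
    results.save(outdir)
    return results
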