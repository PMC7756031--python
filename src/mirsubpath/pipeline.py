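"""End-to-end orchestration: DE -> UPEM -> mining -> CMGN -> modules -> survival.

All randomness flows from a single root seed through per-stage derived
seeds, so an identical config yields byte-identical reports.  When an
output directory is configured, every intermediate artifact is written
alongside a JSON report of the counts at each stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import io as io_mod
from . import mining as mining_mod
from . import modules as modules_mod
from . import network as network_mod
from . import survival as survival_mod
from . import synth as synth_mod
from . import upem as upem_mod

logger = logging.getLogger(__name__)

_STAGE_SEED_DE_GENES = 101
_STAGE_SEED_DE_MIRNAS = 103


@dataclass
class PipelineConfig:
    """All stage parameters plus seed and output directory."""

    gene_fdr: float = 0.001
    mirna_fdr: float = 0.05
    n_perm: int = 100
    mining_n: int = 1
    mining_s: int = 10
    subpathway_fdr: float = 0.001
    corr_threshold: float = -0.7
    k: int = 4
    module_p: float = 1e-4
    annotation_min: float = 0.7
    km_alpha: float = 0.05
    min_present: float = 0.6
    search_combinations: bool = False
    max_subset_size: int | None = None
    include_mirnas_in_survival: bool = False
    evidence: str = "all"
    genome_genes: int | None = None   # default: molecules in the gene matrix
    genome_mirnas: int | None = None
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if not 0 < self.gene_fdr <= 1 or not 0 < self.mirna_fdr <= 1:
            raise ValueError("FDR thresholds must be in (0, 1]")
        if not 0 < self.subpathway_fdr <= 1 or not 0 < self.module_p <= 1:
            raise ValueError("significance thresholds must be in (0, 1]")
        if not -1.0 <= self.corr_threshold <= 0.0:
            raise ValueError("corr_threshold must be in [-1, 0]")
        if not 0.0 <= self.annotation_min <= 1.0:
            raise ValueError("annotation_min must be in [0, 1]")
        mining_mod.MiningParams(n=self.mining_n, s=self.mining_s)
        modules_mod.ModuleParams(k=self.k)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


@dataclass
class RunReport:
    """Counts at every stage plus handles to the in-memory artifacts."""

    counts: dict[str, Any]
    signature: de_mod.SignatureSet
    gene_de: pd.DataFrame
    mirna_de: pd.DataFrame
    subpathways: list[mining_mod.Subpathway]
    significant_subpathways: list[mining_mod.Subpathway]
    network: Any
    node_stats: pd.DataFrame
    powerlaw: network_mod.PowerLawFit
    group_comparison: pd.DataFrame | None
    correlations: pd.DataFrame
    all_modules: list[modules_mod.NetworkModule]
    modules: list[modules_mod.NetworkModule]
    annotations: pd.DataFrame
    survival_report: pd.DataFrame
    search_results: dict[str, pd.DataFrame] = field(default_factory=dict)

    def counts_json(self) -> str:
        return json.dumps(self.counts, sort_keys=True, indent=2, default=float)


def _load_inputs(paths: dict[str, str]) -> synth_mod.Bundle:
    gene_expr = io_mod.read_expression(paths["genes"])
    mirna_expr = io_mod.read_expression(paths["mirnas"])
    labels = io_mod.read_labels(paths["labels"])
    pathways = io_mod.read_pathways(paths["pathways"])
    targets = io_mod.read_targets(paths["targets"])
    survival = io_mod.read_survival(paths["survival"]) if "survival" in paths else None
    spec = synth_mod.SyntheticSpec()  # placeholder spec; real inputs supplied
    return synth_mod.Bundle(
        spec, pathways, synth_mod.GroundTruth(), gene_expr, mirna_expr, labels,
        targets, survival,
    )


def run_pipeline(
    bundle: synth_mod.Bundle,
    config: PipelineConfig = PipelineConfig(),
    known_nodes: list[str] | None = None,
) -> RunReport:
    """Execute every stage on an input bundle and report stage counts."""
    config.validate()
    counts: dict[str, Any] = {}

    # 1. differential expression
    gene_de = de_mod.differential_expression(
        bundle.gene_expr, bundle.labels, fdr_threshold=config.gene_fdr,
        n_perm=config.n_perm, seed=(config.seed * 1000 + _STAGE_SEED_DE_GENES) % (2**31),
    )
    mirna_de = de_mod.differential_expression(
        bundle.mirna_expr, bundle.labels, fdr_threshold=config.mirna_fdr,
        n_perm=config.n_perm, seed=(config.seed * 1000 + _STAGE_SEED_DE_MIRNAS) % (2**31),
    )
    signature = de_mod.build_signature(
        gene_de, mirna_de, gene_fdr=config.gene_fdr, mirna_fdr=config.mirna_fdr
    )
    counts["de_genes"] = len(signature.de_genes)
    counts["de_mirnas"] = len(signature.de_mirnas)

    # 2. UPEM construction
    upems = [
        upem_mod.embed_mirnas(pw, bundle.targets, evidence=config.evidence)
        for pw in bundle.pathways
    ]
    background = upem_mod.build_background(
        upems,
        config.genome_genes or bundle.gene_expr.n_molecules,
        config.genome_mirnas or bundle.mirna_expr.n_molecules,
    )
    counts["pathways"] = len(upems)
    counts["background_total"] = background.total

    # 3. subpathway mining + scoring
    params = mining_mod.MiningParams(n=config.mining_n, s=config.mining_s)
    subpathways = mining_mod.mine_subpathways(upems, signature, params)
    scored, significant = mining_mod.score_subpathways(
        subpathways, background, signature, fdr_threshold=config.subpathway_fdr
    )
    counts["subpathways_extracted"] = len(scored)
    counts["subpathways_significant"] = len(significant)

    # 4. CMGN + anticorrelation + topology
    graph = network_mod.merge_network(significant)
    kinds = dict(graph.nodes(data="kind"))
    counts["network_nodes"] = graph.number_of_nodes()
    counts["network_genes"] = sum(1 for k in kinds.values() if k == io_mod.GENE)
    counts["network_mirnas"] = sum(1 for k in kinds.values() if k == io_mod.MIRNA)
    counts["network_edges"] = graph.number_of_edges()
    if graph.number_of_nodes():
        correlations = network_mod.mark_anticorrelation(
            graph, bundle.gene_expr, bundle.mirna_expr, threshold=config.corr_threshold
        )
    else:
        correlations = pd.DataFrame(
            columns=["mirna_id", "gene_id", "pearson_r", "anticorrelated"])
    counts["anticorrelated_edges"] = int(correlations["anticorrelated"].sum()) if len(
        correlations) else 0
    if known_nodes is not None:
        network_mod.mark_known_disease(graph, known_nodes)
    node_stats, powerlaw, comparison = network_mod.topology_stats(graph, known_nodes)
    counts["powerlaw_slope"] = None if np.isnan(powerlaw.slope) else round(powerlaw.slope, 6)
    counts["powerlaw_r_squared"] = (
        None if np.isnan(powerlaw.r_squared) else round(powerlaw.r_squared, 6)
    )

    # 5. clique-percolation modules
    all_modules = modules_mod.cpm_communities(graph, modules_mod.ModuleParams(k=config.k))
    kept = modules_mod.filter_mirna_mrna_modules(all_modules)
    annotations = modules_mod.annotate_modules(
        kept, significant, p_threshold=config.module_p, min_annotation=config.annotation_min
    )
    counts["modules_total"] = len(all_modules)
    counts["modules_mirna_mrna"] = len(kept)
    counts["modules_annotated"] = (
        int(annotations.groupby("module_id")["annotated"].any().sum())
        if len(annotations) else 0
    )

    # 6. survival evaluation per module
    survival_rows = []
    search_results: dict[str, pd.DataFrame] = {}
    if bundle.survival is not None:
        for mod in kept:
            node_kinds = {n: kinds.get(n, io_mod.GENE) for n in mod.nodes}
            genes = [n for n in sorted(mod.nodes) if node_kinds[n] == io_mod.GENE]
            expr = bundle.gene_expr
            mols: list[str] = genes
            if config.include_mirnas_in_survival:
                expr = io_mod.concat_expression(bundle.gene_expr, bundle.mirna_expr)
                mols = sorted(mod.nodes)
            try:
                _, km = survival_mod.module_km(
                    mols, expr, bundle.survival, min_present=config.min_present
                )
                p = km.p_value
            except ValueError as exc:
                logger.info("module %s survival skipped: %s", mod.module_id, exc)
                p = float("nan")
            survival_rows.append(
                {
                    "module_id": mod.module_id,
                    "n_molecules": mod.size,
                    "n_genes": len(genes),
                    "logrank_p": p,
                    "significant": bool(np.isfinite(p) and p < config.km_alpha),
                }
            )
            if config.search_combinations and genes:
                try:
                    search_results[mod.module_id] = survival_mod.best_signature_search(
                        genes, bundle.gene_expr, bundle.survival,
                        max_subset_size=config.max_subset_size,
                    )
                except ValueError as exc:
                    logger.info("module %s search skipped: %s", mod.module_id, exc)
    survival_report = pd.DataFrame(
        survival_rows,
        columns=["module_id", "n_molecules", "n_genes", "logrank_p", "significant"],
    )
    counts["modules_prognostic"] = (
        int(survival_report["significant"].sum()) if len(survival_report) else 0
    )

    report = RunReport(
        counts=counts,
        signature=signature,
        gene_de=gene_de,
        mirna_de=mirna_de,
        subpathways=scored,
        significant_subpathways=significant,
        network=graph,
        node_stats=node_stats,
        powerlaw=powerlaw,
        group_comparison=comparison,
        correlations=correlations,
        all_modules=all_modules,
        modules=kept,
        annotations=annotations,
        survival_report=survival_report,
        search_results=search_results,
    )
    if config.outdir:
        _write_artifacts(report, bundle, config)
    return report


def _write_artifacts(report: RunReport, bundle: synth_mod.Bundle,
                     config: PipelineConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    (out / "report.json").write_text(report.counts_json() + "\n")
    report.gene_de.reset_index(drop=True).to_csv(out / "de_genes.tsv", sep="\t", index=False)
    report.mirna_de.reset_index(drop=True).to_csv(out / "de_mirnas.tsv", sep="\t", index=False)
    io_mod.write_table(mining_mod.subpathway_table(report.subpathways),
                       out / "subpathways.tsv")
    if report.network.number_of_nodes():
        io_mod.write_network(report.network, out / "cmgn.graphml")
    io_mod.write_table(report.node_stats, out / "node_stats.tsv")
    io_mod.write_table(report.correlations, out / "edge_correlations.tsv")
    mod_rows = [
        {"module_id": m.module_id, "size": m.size, "nodes": "|".join(sorted(m.nodes))}
        for m in report.modules
    ]
    io_mod.write_table(pd.DataFrame(mod_rows, columns=["module_id", "size", "nodes"]),
                       out / "modules.tsv")
    io_mod.write_table(report.annotations, out / "annotations.tsv")
    io_mod.write_table(report.survival_report, out / "survival_report.tsv")


def run_synthetic(
    spec: synth_mod.SyntheticSpec,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[RunReport, synth_mod.Bundle]:
    """Generate a synthetic bundle from ``spec`` and run the pipeline on it."""
    bundle = synth_mod.generate_all(spec)
    report = run_pipeline(bundle, config)
    return report, bundle
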