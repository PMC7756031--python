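"""Model/Results facade over the subpathway-biomarker pipeline.

``SubpathwayModel`` holds the study inputs (expression, labels, pathways,
targets, survival); ``fit()`` executes the full analysis and returns a
``SubpathwayResults`` carrying the signature, scored subpathways, the
miRNA-gene network with topology statistics, clique-percolation modules
and the per-module survival evaluation, with a ``summary()`` table of the
headline counts.  Plotting and recovery scoring hang off the results.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any

import numpy as np

from .io import (
    ConditionLabels,
    ExpressionMatrix,
    MiRTargetTable,
    PathwayGraph,
    SurvivalTable,
    read_expression,
    read_id_list,
    read_labels,
    read_pathways,
    read_survival,
    read_targets,
)
from .pipeline import PipelineConfig, RunReport, run_pipeline
from .synth import Bundle, GroundTruth, SyntheticSpec, generate_all


class SubpathwayModel:
    """The miRNA-mediated subpathway biomarker analysis, unfitted.

    Parameters mirror the pipeline configuration; see
    :class:`~mirsubpath.pipeline.PipelineConfig` for the stage thresholds
    (gene/miRNA FDR, lenient-distance n and s, subpathway FDR, correlation
    mark, clique size k, annotation thresholds, KM alpha).
    """

    def __init__(
        self,
        gene_expr: ExpressionMatrix,
        mirna_expr: ExpressionMatrix,
        labels: ConditionLabels,
        pathways: list[PathwayGraph],
        targets: MiRTargetTable,
        survival: SurvivalTable | None = None,
        known_nodes: list[str] | None = None,
        ground_truth: GroundTruth | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        labels.validate_against(gene_expr)
        labels.validate_against(mirna_expr)
        self.bundle = Bundle(
            SyntheticSpec(), pathways, ground_truth or GroundTruth(),
            gene_expr, mirna_expr, labels, targets, survival,
        )
        self.known_nodes = known_nodes
        self.config = config or PipelineConfig()

    @classmethod
    def from_synthetic(
        cls,
        spec: SyntheticSpec,
        config: PipelineConfig | None = None,
        known_nodes: list[str] | None = None,
    ) -> "SubpathwayModel":
        """Build the model from a synthetic cohort with known ground truth."""
        bundle = generate_all(spec)
        model = cls.__new__(cls)
        model.bundle = bundle
        model.known_nodes = known_nodes
        model.config = config or PipelineConfig(seed=spec.seed)
        return model

    @classmethod
    def from_files(
        cls,
        genes: str,
        mirnas: str,
        labels: str,
        pathways: str,
        targets: str,
        survival: str | None = None,
        known: str | None = None,
        config: PipelineConfig | None = None,
    ) -> "SubpathwayModel":
        return cls(
            gene_expr=read_expression(genes),
            mirna_expr=read_expression(mirnas),
            labels=read_labels(labels),
            pathways=read_pathways(pathways),
            targets=read_targets(targets),
            survival=read_survival(survival) if survival else None,
            known_nodes=read_id_list(known) if known else None,
            config=config,
        )

    def fit(self, seed: int | None = None, **config_overrides: Any) -> "SubpathwayResults":
        config = replace(self.config, **config_overrides)
        if seed is not None:
            config = replace(config, seed=seed)
        report = run_pipeline(self.bundle, config, known_nodes=self.known_nodes)
        return SubpathwayResults(self, report, config)


class SubpathwayResults:
    """Fitted pipeline artifacts with summary, plotting and recovery scoring."""

    def __init__(self, model: SubpathwayModel, report: RunReport,
                 config: PipelineConfig) -> None:
        self.model = model
        self.report = report
        self.config = config
        # statsmodels-style accessors
        self.signature = report.signature
        self.subpathways = report.subpathways
        self.significant_subpathways = report.significant_subpathways
        self.network = report.network
        self.node_stats = report.node_stats
        self.powerlaw = report.powerlaw
        self.modules = report.modules
        self.annotations = report.annotations
        self.survival_report = report.survival_report
        self.counts = report.counts

    def summary(self) -> str:
        """Plain-text table of the headline counts of every stage."""
        c = self.counts
        lines = [
            "miRNA-mediated subpathway biomarker analysis",
            "=" * 52,
            f"{'DE genes (signature)':38s} {c['de_genes']:>10}",
            f"{'DE miRNAs (signature)':38s} {c['de_mirnas']:>10}",
            f"{'pathways (UPEMs)':38s} {c['pathways']:>10}",
            f"{'subpathways extracted':38s} {c['subpathways_extracted']:>10}",
            f"{'subpathways significant':38s} {c['subpathways_significant']:>10}",
            f"{'network nodes (genes/miRNAs)':38s} "
            f"{c['network_genes']:>5}/{c['network_mirnas']:<5}",
            f"{'network edges':38s} {c['network_edges']:>10}",
            f"{'anticorrelated edges':38s} {c['anticorrelated_edges']:>10}",
            f"{'modules (all / miRNA-mRNA)':38s} "
            f"{c['modules_total']:>5}/{c['modules_mirna_mrna']:<5}",
            f"{'prognostic modules (log-rank p<alpha)':38s} {c['modules_prognostic']:>10}",
        ]
        if c.get("powerlaw_slope") is not None:
            lines.append(
                f"{'degree power-law slope / R^2':38s} "
                f"{c['powerlaw_slope']:>8.3f}/{c['powerlaw_r_squared']:<6.3f}"
            )
        lines.append("=" * 52)
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # recovery scoring against synthetic ground truth

    def recovery(self) -> dict[str, float]:
        """Score recovery of the planted structure (synthetic inputs only)."""
        gt = self.model.bundle.ground_truth
        out: dict[str, float] = {}
        if gt.de_genes:
            planted = set(gt.de_genes)
            out["de_gene_recall"] = len(planted & self.signature.de_genes) / len(planted)
        if gt.de_mirnas:
            planted = set(gt.de_mirnas)
            out["de_mirna_recall"] = len(planted & self.signature.de_mirnas) / len(planted)
        if gt.planted_subregions:
            recovered = 0
            for region in gt.planted_subregions.values():
                region_set = set(region)
                if any(
                    len(region_set & sp.nodes) >= 0.9 * len(region_set)
                    for sp in self.significant_subpathways
                ):
                    recovered += 1
            out["subregion_recovery"] = recovered / len(gt.planted_subregions)
            if self.subpathways:
                top = self.subpathways[0]
                out["top_subpathway_planted"] = float(
                    any(
                        len(set(region) & top.nodes) >= 0.5 * len(region)
                        for region in gt.planted_subregions.values()
                    )
                )
        if gt.anticorr_pairs:
            flagged = {
                (row.mirna_id, row.gene_id)
                for row in self.report.correlations.itertuples()
                if row.anticorrelated
            }
            in_network = [
                pair for pair in gt.anticorr_pairs
                if self.network.has_edge(*pair)
            ]
            if in_network:
                out["anticorr_flag_rate"] = sum(
                    1 for pair in in_network if tuple(pair) in flagged
                ) / len(in_network)
        if gt.prognostic and len(self.survival_report):
            prognostic = set(gt.prognostic)
            hits = [
                row
                for row, mod in zip(self.survival_report.itertuples(), self.modules)
                if prognostic & mod.nodes and row.significant
            ]
            out["prognostic_module_recovered"] = float(bool(hits))
        return out

    # ------------------------------------------------------------------
    # plotting

    def plot_degree_distribution(self, ax=None):
        """Log-log degree distribution with the fitted power law."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        degrees = self.node_stats["degree"].to_numpy()
        uniq, counts = np.unique(degrees[degrees >= 1], return_counts=True)
        ax.loglog(uniq, counts, "o", label="nodes")
        if np.isfinite(self.powerlaw.slope):
            xs = np.linspace(np.log10(uniq.min()), np.log10(uniq.max()), 50)
            ax.plot(
                10**xs,
                10 ** (self.powerlaw.slope * xs + self.powerlaw.intercept),
                "-",
                label=(f"slope {self.powerlaw.slope:.3f}, "
                       f"$R^2$ {self.powerlaw.r_squared:.3f}"),
            )
        ax.set_xlabel("degree")
        ax.set_ylabel("number of nodes")
        ax.legend()
        return ax

    def plot_km(self, module_id: str, ax=None):
        """Kaplan-Meier curves of the high/low risk arms of one module."""
        import matplotlib.pyplot as plt

        from .io import GENE
        from .survival import module_km

        if self.model.bundle.survival is None:
            raise ValueError("no survival table was supplied")
        mod = next((m for m in self.modules if m.module_id == module_id), None)
        if mod is None:
            raise KeyError(f"unknown module {module_id!r}")
        kinds = dict(self.network.nodes(data="kind"))
        genes = [n for n in sorted(mod.nodes) if kinds.get(n, GENE) == GENE]
        _, km = module_km(genes, self.model.bundle.gene_expr,
                          self.model.bundle.survival, min_present=0.0)
        if ax is None:
            _, ax = plt.subplots()
        for label, curve in km.curves.items():
            ax.step(curve.index, curve["survival"], where="post", label=f"{label} risk")
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        ax.set_title(f"{module_id}: log-rank p = {km.p_value:.3g}")
        ax.legend()
        return ax
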