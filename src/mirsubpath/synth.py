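"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates a two-condition microarray study of a solid tumor:
log-scale gene and miRNA expression for case vs. control samples, undirected
pathway graphs with planted differentially-expressed dense subregions,
a validated miRNA-target table that includes planted strongly anticorrelated
(miRNA, target) pairs, and survival times whose hazard depends on a planted
prognostic molecule set.  Every operation is fully deterministic under the
spec seed; the ground-truth object is sufficient to score recovery of each
downstream stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    CASE,
    CONTROL,
    GENE,
    MIRNA,
    ConditionLabels,
    ExpressionMatrix,
    MiRTargetTable,
    PathwayGraph,
    SurvivalTable,
    write_expression,
    write_labels,
    write_pathways,
    write_survival,
    write_targets,
)

# sub-seeds so each operation draws from an independent, reproducible stream
_SEED_PATHWAYS, _SEED_EXPRESSION, _SEED_TARGETS, _SEED_SURVIVAL = 11, 13, 17, 19

#: baseline log-expression level and spread (log2-microarray-like units)
BASELINE_MEAN = 8.0
BASELINE_SD = 1.0
#: extra edge probability inside a planted subregion (makes it clique-rich)
PLANT_DENSITY = 0.6
#: size of each planted subregion (connected, DE-dense)
PLANT_SIZE = 10
#: relative noise of the mirrored profile of a planted anticorrelated miRNA
ANTICORR_NOISE = 0.1
#: baseline hazard: median survival of 24 months for a null patient
BASELINE_HAZARD = np.log(2.0) / 24.0


@dataclass
class SyntheticSpec:
    """Study-condition parameters for the synthetic cohort."""

    n_genes: int = 60
    n_mirnas: int = 12
    n_case: int = 20
    n_control: int = 20
    n_pathways: int = 6
    pathway_size_range: tuple[int, int] = (12, 25)
    planted_subpathway_fraction: float = 1.0 / 3.0
    de_effect: float = 2.0
    noise_sd: float = 0.5
    target_density: float = 2.0
    anticorr_pairs: int = 3
    survival_beta: float = 0.8
    n_prognostic: int = 4
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_case", "n_control", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.planted_subpathway_fraction <= 1.0:
            raise ValueError("planted_subpathway_fraction must be in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.pathway_size_range
        if lo < 3:
            raise ValueError("pathway_size_range minimum must be >= 3")
        if lo > hi:
            raise ValueError("pathway_size_range must be (min, max) with min <= max")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(1, self.n_genes + 1)]

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR-{i:04d}" for i in range(1, self.n_mirnas + 1)]


def test_scale_spec(seed: int = 0) -> SyntheticSpec:
    """Small cohort for fast tests (~60 genes, 12 miRNAs, 6 pathways)."""
    return SyntheticSpec(seed=seed)


def paper_scale_spec(seed: int = 0) -> SyntheticSpec:
    """Cohort matching the magnitude of a genome-wide two-group study
    (thousands of genes, hundreds of miRNAs, 343 pathways)."""
    return SyntheticSpec(
        n_genes=6000,
        n_mirnas=400,
        n_case=20,
        n_control=20,
        n_pathways=343,
        pathway_size_range=(20, 60),
        planted_subpathway_fraction=0.3,
        de_effect=2.0,
        noise_sd=0.5,
        target_density=3.0,
        anticorr_pairs=100,
        survival_beta=0.8,
        censor_rate=0.3,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Planted structure recorded by the generator, for recovery scoring."""

    planted_subregions: dict[str, list[str]] = field(default_factory=dict)
    de_genes: list[str] = field(default_factory=list)
    de_mirnas: list[str] = field(default_factory=list)
    anticorr_pairs: list[tuple[str, str]] = field(default_factory=list)
    anticorr_targets: dict[str, list[str]] = field(default_factory=dict)
    prognostic: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["anticorr_pairs"] = [list(p) for p in self.anticorr_pairs]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["anticorr_pairs"] = [tuple(p) for p in payload["anticorr_pairs"]]
        return cls(**payload)


def _ensure_connected(graph: nx.Graph, nodes: list) -> None:
    """Add chaining edges until ``nodes`` induce a connected subgraph."""
    sub = graph.subgraph(nodes)
    comps = [sorted(c) for c in nx.connected_components(sub)]
    comps.sort()
    for prev, nxt in zip(comps, comps[1:]):
        graph.add_edge(prev[0], nxt[0])


def generate_pathways(spec: SyntheticSpec) -> tuple[list[PathwayGraph], GroundTruth]:
    """Build connected pathway graphs and plant DE-dense subregions.

    Pathways are small-world graphs (Watts–Strogatz wiring) over genes
    sampled from the genome pool.  A fraction of pathways receives a planted
    subregion: a connected node set of size >= 10 densified with extra edges
    so it is clique-rich.  Planted anticorrelated miRNAs are each assigned a
    target triangle inside one planted subregion.
    """
    spec.validate()
    rng = np.random.default_rng((spec.seed, _SEED_PATHWAYS))
    lo, hi = spec.pathway_size_range
    n_planted = int(round(spec.planted_subpathway_fraction * spec.n_pathways))
    if n_planted > 0 and hi < PLANT_SIZE:
        raise ValueError(
            f"pathway_size_range max {hi} too small to plant subregions of {PLANT_SIZE}"
        )
    planted_idx = set(
        int(i) for i in rng.choice(spec.n_pathways, size=n_planted, replace=False)
    )
    gene_pool = np.array(spec.gene_ids)
    gt = GroundTruth()
    pathways: list[PathwayGraph] = []
    subregion_lists: list[list[str]] = []
    for i in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if i in planted_idx:
            size = max(size, PLANT_SIZE)
        size = min(size, spec.n_genes)
        k = min(4, size - 1)
        base = nx.connected_watts_strogatz_graph(
            size, k if k % 2 == 0 else k + 1 if k + 1 < size else k, 0.1,
            seed=int(rng.integers(2**31)),
        )
        genes = rng.choice(gene_pool, size=size, replace=False)
        mapping = {j: str(genes[j]) for j in range(size)}
        g = nx.relabel_nodes(base, mapping)
        pid = f"p{i + 1:03d}"
        if i in planted_idx:
            start = int(rng.integers(size))
            idxs = [(start + j) % size for j in range(PLANT_SIZE)]
            region = [mapping[j] for j in idxs]
            for a in range(len(region)):
                for b in range(a + 1, len(region)):
                    if rng.random() < PLANT_DENSITY:
                        g.add_edge(region[a], region[b])
            _ensure_connected(g, region)
            gt.planted_subregions[pid] = sorted(region)
            subregion_lists.append(sorted(region))
        pathways.append(PathwayGraph(pid, f"synthetic pathway {pid}", g))

    # planted anticorrelated miRNAs: round-robin over planted subregions,
    # each targeting a triangle of genes so it can join a 4-clique community
    n_ac = min(spec.anticorr_pairs, spec.n_mirnas)
    graphs = {pw.pathway_id: pw.graph for pw in pathways}
    region_pids = sorted(gt.planted_subregions)
    for j in range(n_ac):
        mirna = spec.mirna_ids[j]
        if region_pids:
            pid = region_pids[j % len(region_pids)]
            region = gt.planted_subregions[pid]
            trio = [str(x) for x in rng.choice(region, size=min(3, len(region)), replace=False)]
            g = graphs[pid]
            for a in range(len(trio)):
                for b in range(a + 1, len(trio)):
                    g.add_edge(trio[a], trio[b])
        else:
            trio = [str(x) for x in rng.choice(gene_pool, size=3, replace=False)]
        gt.anticorr_targets[mirna] = sorted(trio)
        gt.anticorr_pairs.append((mirna, trio[0]))
    gt.de_genes = sorted(set().union(*subregion_lists)) if subregion_lists else []
    gt.de_mirnas = sorted(gt.anticorr_targets)
    # prognostic set: genes of the first planted subregion (fallback: random genes)
    if region_pids:
        pool = gt.planted_subregions[region_pids[0]]
    else:
        pool = list(gene_pool)
    n_prog = min(spec.n_prognostic, len(pool))
    gt.prognostic = sorted(str(x) for x in rng.choice(pool, size=n_prog, replace=False))
    return pathways, gt


def generate_expression(
    spec: SyntheticSpec,
    pathways: list[PathwayGraph],
    ground_truth: GroundTruth,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ConditionLabels]:
    """Two-condition log-expression for genes and miRNAs.

    Planted DE genes get a case-vs-control mean shift of ``de_effect``;
    planted anticorrelated miRNAs mirror their partner gene's profile around
    their own baseline (Pearson r ~ -1), inheriting a -de_effect shift; all
    other molecules have zero shift and Gaussian noise ``noise_sd``.
    """
    spec.validate()
    if spec.n_case < 3 or spec.n_control < 3:
        raise ValueError("need at least 3 case and 3 control samples")
    rng = np.random.default_rng((spec.seed, _SEED_EXPRESSION))
    case_ids = [f"case{i:03d}" for i in range(1, spec.n_case + 1)]
    ctrl_ids = [f"ctrl{i:03d}" for i in range(1, spec.n_control + 1)]
    samples = case_ids + ctrl_ids
    n = len(samples)

    genes = spec.gene_ids
    gvals = (
        rng.normal(BASELINE_MEAN, BASELINE_SD, size=(spec.n_genes, 1))
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    de_rows = [gene_pos[g] for g in ground_truth.de_genes]
    gvals[np.array(de_rows, dtype=int)[:, None], np.arange(spec.n_case)[None, :]] += (
        spec.de_effect if de_rows else 0.0
    )
    gene_df = pd.DataFrame(gvals, index=genes, columns=samples)

    mirnas = spec.mirna_ids
    mvals = (
        rng.normal(BASELINE_MEAN, BASELINE_SD, size=(spec.n_mirnas, 1))
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_mirnas, n))
    )
    for mirna, partner in ground_truth.anticorr_pairs:
        i = mirnas.index(mirna)
        prof = gene_df.loc[partner].to_numpy()
        baseline = float(np.mean(mvals[i]))
        mvals[i] = (
            baseline
            - (prof - prof.mean())
            + rng.normal(0.0, ANTICORR_NOISE * spec.noise_sd, size=n)
        )
    mirna_df = pd.DataFrame(mvals, index=mirnas, columns=samples)

    labels = ConditionLabels(
        pd.Series([CASE] * spec.n_case + [CONTROL] * spec.n_control, index=samples)
    )
    gene_em = ExpressionMatrix(gene_df, pd.Series(GENE, index=genes))
    mirna_em = ExpressionMatrix(mirna_df, pd.Series(MIRNA, index=mirnas))
    return gene_em, mirna_em, labels


def generate_targets(
    spec: SyntheticSpec,
    pathways: list[PathwayGraph],
    ground_truth: GroundTruth | None = None,
) -> MiRTargetTable:
    """Validated-target table: Poisson(target_density) targets per miRNA,
    biased toward pathway genes; every planted anticorrelated pair included."""
    spec.validate()
    rng = np.random.default_rng((spec.seed, _SEED_TARGETS))
    pathway_genes = sorted(set().union(*(set(pw.graph.nodes) for pw in pathways)))
    pool = spec.gene_ids
    rows: list[tuple[str, str, str]] = []
    for mirna in spec.mirna_ids:
        n_t = int(rng.poisson(spec.target_density))
        for _ in range(n_t):
            source = pathway_genes if (pathway_genes and rng.random() < 0.8) else pool
            gene = str(source[int(rng.integers(len(source)))])
            evidence = "low_throughput" if rng.random() < 0.2 else "high_throughput"
            rows.append((mirna, gene, evidence))
    if ground_truth is not None:
        for mirna, targets in sorted(ground_truth.anticorr_targets.items()):
            for gene in targets:
                rows.append((mirna, gene, "low_throughput"))
    df = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "evidence"])
    return MiRTargetTable(df)


def generate_survival(
    spec: SyntheticSpec,
    expression: ExpressionMatrix,
    prognostic_set: list[str],
) -> SurvivalTable:
    """Exponential proportional-hazards event times.

    The linear predictor is ``survival_beta`` times the sum of z-scored
    expression over the prognostic molecules (z-scoring keeps the hazard
    scale independent of the baseline log-expression level).  Censoring is
    independent exponential, tuned so the expected censored fraction is
    approximately ``censor_rate``.
    """
    spec.validate()
    missing = sorted(set(prognostic_set) - set(expression.molecule_ids))
    if missing:
        raise ValueError(f"prognostic molecule absent from matrix: {missing[0]!r}")
    rng = np.random.default_rng((spec.seed, _SEED_SURVIVAL))
    samples = expression.sample_ids
    if prognostic_set:
        X = expression.values.loc[list(prognostic_set)].to_numpy(dtype=float)
        sd = X.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        lp = spec.survival_beta * Z.sum(axis=0)
    else:
        lp = np.zeros(len(samples))
    rate = BASELINE_HAZARD * np.exp(lp)
    event_time = rng.exponential(1.0 / rate)
    if spec.censor_rate > 0:
        geo_rate = float(np.exp(np.mean(np.log(rate))))
        censor_hazard = geo_rate * spec.censor_rate / (1.0 - spec.censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard, size=len(samples))
    else:
        censor_time = np.full(len(samples), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    df = pd.DataFrame({"time_months": time, "event": event}, index=samples)
    return SurvivalTable(df)


@dataclass
class Bundle:
    """All pipeline inputs generated from one spec, plus ground truth."""

    spec: SyntheticSpec
    pathways: list[PathwayGraph]
    ground_truth: GroundTruth
    gene_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    labels: ConditionLabels
    targets: MiRTargetTable
    survival: SurvivalTable


def generate_all(spec: SyntheticSpec) -> Bundle:
    """Run every generator stage in order under the spec seed."""
    pathways, gt = generate_pathways(spec)
    gene_expr, mirna_expr, labels = generate_expression(spec, pathways, gt)
    targets = generate_targets(spec, pathways, gt)
    survival = generate_survival(spec, gene_expr, gt.prognostic)
    return Bundle(spec, pathways, gt, gene_expr, mirna_expr, labels, targets, survival)


def write_bundle(bundle: Bundle, outdir: str | Path) -> None:
    """Emit all inputs as TSV plus ground_truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.gene_expr, out / "genes.tsv")
    write_expression(bundle.mirna_expr, out / "mirnas.tsv")
    write_labels(bundle.labels, out / "labels.tsv")
    write_pathways(bundle.pathways, out / "pathways.tsv")
    write_targets(bundle.targets, out / "targets.tsv")
    write_survival(bundle.survival, out / "survival.tsv")
    bundle.ground_truth.to_json(out / "ground_truth.json")
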