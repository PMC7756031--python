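"""Comprehensive miRNA-gene network (CMGN): merge, correlation marks, topology.

The CMGN is the union of nodes and edges over all significant subpathways.
Each edge remembers its subpathway origins; miRNA-gene edges are flagged
when the Pearson correlation between the miRNA and gene expression profiles
is below a (negative) threshold.  Topology statistics cover degree,
normalized betweenness centrality, a log-log least-squares power-law fit of
the degree distribution, and a known-disease vs. other node comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import GENE, MIRNA, ExpressionMatrix
from .mining import Subpathway

logger = logging.getLogger(__name__)


def merge_network(subpathways: list[Subpathway]) -> nx.Graph:
    """Union of significant subpathways; per-edge ``origins`` lists sources.

    Order-independent: permuting the input yields an identical graph.
    """
    g = nx.Graph()
    for sp in sorted(subpathways, key=lambda s: s.subpathway_id):
        for node, attrs in sp.graph.nodes(data=True):
            if node not in g:
                g.add_node(node, kind=attrs.get("kind", GENE))
        for a, b in sp.graph.edges():
            if g.has_edge(a, b):
                g.edges[a, b]["origins"].append(sp.subpathway_id)
            else:
                g.add_edge(a, b, origins=[sp.subpathway_id])
    for a, b in g.edges():
        g.edges[a, b]["origins"] = sorted(g.edges[a, b]["origins"])
    return g


def mark_known_disease(graph: nx.Graph, known_nodes: list[str] | set[str]) -> None:
    known = set(known_nodes)
    for node in graph.nodes:
        graph.nodes[node]["known_disease"] = node in known


def mark_anticorrelation(
    graph: nx.Graph,
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    threshold: float = -0.7,
) -> pd.DataFrame:
    """Flag miRNA-gene edges with Pearson r below ``threshold``.

    Correlations use the intersection of the two matrices' samples (logged).
    Zero-variance profiles leave r undefined and the edge unflagged.
    Returns a frame of per-edge correlations; the graph gains ``pearson_r``
    and ``anticorrelated`` edge attributes.
    """
    shared = [s for s in gene_expr.sample_ids if s in set(mirna_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    logger.info("anticorrelation over %d shared samples", len(shared))
    gvals = gene_expr.values[shared]
    mvals = mirna_expr.values[shared]
    kinds = dict(graph.nodes(data="kind"))
    rows = []
    for a, b in graph.edges():
        ka, kb = kinds.get(a), kinds.get(b)
        if {ka, kb} != {GENE, MIRNA}:
            continue
        mirna, gene = (a, b) if ka == MIRNA else (b, a)
        if mirna not in mvals.index or gene not in gvals.index:
            graph.edges[a, b]["anticorrelated"] = False
            continue
        x = mvals.loc[mirna].to_numpy(dtype=float)
        y = gvals.loc[gene].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            logger.info("zero-variance profile on edge (%s, %s); unflagged", mirna, gene)
            graph.edges[a, b]["anticorrelated"] = False
            rows.append({"mirna_id": mirna, "gene_id": gene, "pearson_r": np.nan,
                         "anticorrelated": False})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        flagged = bool(r < threshold)
        graph.edges[a, b]["pearson_r"] = r
        graph.edges[a, b]["anticorrelated"] = flagged
        rows.append({"mirna_id": mirna, "gene_id": gene, "pearson_r": r,
                     "anticorrelated": flagged})
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "pearson_r", "anticorrelated"])


def correlation_matrix(
    graph: nx.Graph, gene_expr: ExpressionMatrix, mirna_expr: ExpressionMatrix
) -> pd.DataFrame:
    """Full miRNA-vs-gene Pearson matrix over network molecules (optional output)."""
    shared = [s for s in gene_expr.sample_ids if s in set(mirna_expr.sample_ids)]
    kinds = dict(graph.nodes(data="kind"))
    mirnas = sorted(n for n, k in kinds.items() if k == MIRNA and n in mirna_expr.values.index)
    genes = sorted(n for n, k in kinds.items() if k == GENE and n in gene_expr.values.index)
    m = mirna_expr.values.loc[mirnas, shared].to_numpy(dtype=float)
    g = gene_expr.values.loc[genes, shared].to_numpy(dtype=float)
    mz = (m - m.mean(axis=1, keepdims=True))
    gz = (g - g.mean(axis=1, keepdims=True))
    denom = np.outer(np.linalg.norm(mz, axis=1), np.linalg.norm(gz, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (mz @ gz.T) / denom
    return pd.DataFrame(corr, index=mirnas, columns=genes)


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares line of log10(node count) on log10(degree)."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if np.isfinite(self.r_squared) and not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")


def fit_degree_powerlaw(graph: nx.Graph) -> PowerLawFit:
    """Fit count(d) ~ C * d^slope on raw (unbinned) degree counts, degree >= 1."""
    degrees = np.array([d for _, d in graph.degree() if d >= 1])
    if degrees.size == 0:
        return PowerLawFit(np.nan, np.nan, np.nan)
    uniq, counts = np.unique(degrees, return_counts=True)
    if len(uniq) < 2:
        return PowerLawFit(np.nan, np.nan, np.nan)
    x = np.log10(uniq.astype(float))
    y = np.log10(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(float(slope), float(intercept), float(r2))


def topology_stats(
    graph: nx.Graph, known_nodes: list[str] | set[str] | None = None
) -> tuple[pd.DataFrame, PowerLawFit, pd.DataFrame | None]:
    """Per-node degree and normalized betweenness, power-law fit, group comparison.

    The group comparison (known-disease vs. other nodes) reports mean, SEM
    and a two-sided rank-sum p-value for degree and betweenness; it is
    ``None`` when no known-node list is supplied.
    """
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    kinds = dict(graph.nodes(data="kind"))
    stats_df = pd.DataFrame(
        {
            "node_id": sorted(graph.nodes, key=str),
        }
    )
    stats_df["kind"] = [kinds.get(n, GENE) for n in stats_df["node_id"]]
    stats_df["degree"] = [degree[n] for n in stats_df["node_id"]]
    stats_df["betweenness"] = [betweenness[n] for n in stats_df["node_id"]]
    fit = fit_degree_powerlaw(graph)
    comparison = None
    if known_nodes is not None:
        known = set(known_nodes)
        stats_df["known_disease"] = stats_df["node_id"].isin(known)
        rows = []
        for metric in ("degree", "betweenness"):
            a = stats_df.loc[stats_df["known_disease"], metric].to_numpy(dtype=float)
            b = stats_df.loc[~stats_df["known_disease"], metric].to_numpy(dtype=float)
            if len(a) and len(b):
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            else:
                p = np.nan
            rows.append(
                {
                    "metric": metric,
                    "known_mean": float(a.mean()) if len(a) else np.nan,
                    "known_sem": float(stats.sem(a)) if len(a) > 1 else np.nan,
                    "other_mean": float(b.mean()) if len(b) else np.nan,
                    "other_sem": float(stats.sem(b)) if len(b) > 1 else np.nan,
                    "ranksum_p": p,
                }
            )
        comparison = pd.DataFrame(rows)
    return stats_df, fit, comparison
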