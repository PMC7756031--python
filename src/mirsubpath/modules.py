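"""Overlapping community mining by clique percolation and module annotation.

A k-clique community is a maximal union of k-cliques reachable from one
another through chains of k-cliques sharing k-1 nodes; nodes may belong to
several communities.  Communities containing at least one miRNA and one
gene and not contained in any other such community are the miRNA-mRNA
modules.  Modules are annotated against significant subpathways with the
same hypergeometric upper tail used for enrichment, over the universe of
all significant-subpathway nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from networkx.algorithms.community import k_clique_communities

from .io import GENE, MIRNA, infer_kind
from .mining import Subpathway, hypergeom_upper_tail


@dataclass(frozen=True)
class ModuleParams:
    k: int = 4

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")


@dataclass
class NetworkModule:
    """One k-clique community of the network."""

    module_id: str
    nodes: frozenset[str]
    cliques: tuple[frozenset[str], ...] | None = None
    has_mirna: bool = False
    has_gene: bool = False

    @property
    def size(self) -> int:
        return len(self.nodes)


def k_cliques(graph: nx.Graph, k: int, nodes=None) -> list[frozenset[str]]:
    """All k-cliques of the graph (optionally restricted to a node set)."""
    g = graph.subgraph(nodes) if nodes is not None else graph
    found: set[frozenset[str]] = set()
    for maximal in nx.find_cliques(g):
        if len(maximal) >= k:
            for combo in itertools.combinations(sorted(maximal), k):
                found.add(frozenset(combo))
    return sorted(found, key=lambda c: tuple(sorted(c)))


def _node_kind(graph: nx.Graph, node) -> str:
    kind = graph.nodes[node].get("kind")
    return kind if kind in (GENE, MIRNA) else infer_kind(node)


def cpm_communities(
    graph: nx.Graph,
    params: ModuleParams | int = ModuleParams(),
    include_cliques: bool = False,
) -> list[NetworkModule]:
    """Clique-percolation communities of a simple undirected graph.

    Returned modules are sorted by decreasing size then lexicographically
    smallest node, with provisional ids C1..Cn.  ``include_cliques`` also
    enumerates each community's member k-cliques (costly on dense graphs).
    """
    k = params.k if isinstance(params, ModuleParams) else ModuleParams(k=params).k
    communities = [frozenset(c) for c in k_clique_communities(graph, k)]
    communities.sort(key=lambda c: (-len(c), min(c)))
    out = []
    for i, nodes in enumerate(communities, start=1):
        kinds = {_node_kind(graph, n) for n in nodes}
        out.append(
            NetworkModule(
                module_id=f"C{i}",
                nodes=nodes,
                cliques=tuple(k_cliques(graph, k, nodes)) if include_cliques else None,
                has_mirna=MIRNA in kinds,
                has_gene=GENE in kinds,
            )
        )
    return out


def filter_mirna_mrna_modules(modules: list[NetworkModule]) -> list[NetworkModule]:
    """Non-redundant miRNA-mRNA modules.

    Keeps communities with at least one miRNA and one gene, then drops any
    whose node set is contained in another kept module's node set (the
    larger module is retained).  Ids are reassigned M1..Mn by decreasing
    size then lexicographically smallest node.
    """
    mixed = [m for m in modules if m.has_mirna and m.has_gene]
    mixed.sort(key=lambda m: (-m.size, min(m.nodes) if m.nodes else ""))
    kept: list[NetworkModule] = []
    for m in mixed:
        if any(m.nodes <= other.nodes for other in kept):
            continue
        kept.append(m)
    return [
        NetworkModule(
            module_id=f"M{i}",
            nodes=m.nodes,
            cliques=m.cliques,
            has_mirna=m.has_mirna,
            has_gene=m.has_gene,
        )
        for i, m in enumerate(kept, start=1)
    ]


@dataclass(frozen=True)
class OverlapCounts:
    """Counts of the module-vs-subpathway hypergeometric overlap test."""

    m: int  # unique nodes across all significant subpathways
    t: int  # nodes in the chosen subpathway
    n: int  # nodes in the module
    r: int  # common nodes

    def __post_init__(self) -> None:
        if min(self.m, self.t, self.n, self.r) < 0:
            raise ValueError("overlap counts must be non-negative")
        if self.r > min(self.t, self.n):
            raise ValueError("r exceeds min(t, n)")
        if max(self.t, self.n) > self.m:
            raise ValueError("t and n cannot exceed the universe m")


def overlap_p_value(counts: OverlapCounts) -> float:
    """P(overlap >= r) drawing n module nodes from a universe of m."""
    return hypergeom_upper_tail(counts.m, counts.t, counts.n, counts.r)


def annotate_modules(
    modules: list[NetworkModule],
    subpathways: list[Subpathway],
    p_threshold: float = 1e-4,
    min_annotation: float = 0.7,
) -> pd.DataFrame:
    """Module -> subpathway annotations.

    A module is annotated to a subpathway when the overlap p-value is below
    ``p_threshold`` AND the annotation proportion r/n (module nodes found in
    the subpathway) is at least ``min_annotation``.
    """
    universe: set[str] = set()
    for sp in subpathways:
        universe |= sp.nodes
    m = len(universe)
    rows = []
    for mod in modules:
        module_in_universe = mod.nodes & universe
        for sp in subpathways:
            r = len(mod.nodes & sp.nodes)
            counts = OverlapCounts(m=m, t=len(sp.nodes), n=len(module_in_universe), r=r)
            p = overlap_p_value(counts) if counts.n else 1.0
            proportion = r / mod.size if mod.size else 0.0
            rows.append(
                {
                    "module_id": mod.module_id,
                    "subpathway_id": sp.subpathway_id,
                    "m": m,
                    "t": counts.t,
                    "n": counts.n,
                    "r": r,
                    "p_value": p,
                    "annotation_proportion": proportion,
                    "annotated": bool(p < p_threshold and proportion >= min_annotation),
                }
            )
    return pd.DataFrame(rows)
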