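"""Undirected Pathway graphs Embedded by MiRNA (UPEM).

A pathway's gene graph is augmented with miRNA nodes: a miRNA is added iff
at least one of its validated targets is a gene node of the pathway, with
one edge per contained target.  Gene-gene edges are never touched, so
removing the miRNA nodes recovers the original pathway exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import GENE, MIRNA, MiRTargetTable, PathwayGraph


@dataclass
class UPEM:
    """Pathway graph plus embedded miRNA nodes and target edges.

    Every node carries a ``kind`` attribute in {gene, mirna}; miRNA nodes
    have degree >= 1 by construction.
    """

    pathway_id: str
    name: str
    graph: nx.Graph = field(repr=False)

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, k in self.graph.nodes(data="kind") if k == GENE}

    @property
    def mirna_nodes(self) -> set[str]:
        return {n for n, k in self.graph.nodes(data="kind") if k == MIRNA}

    def node_kinds(self) -> dict[str, str]:
        return dict(self.graph.nodes(data="kind"))


def embed_mirnas(
    pathway: PathwayGraph | UPEM,
    targets: MiRTargetTable,
    evidence: str = "all",
) -> UPEM:
    """Embed miRNA nodes into a pathway via their validated targets.

    Idempotent: embedding an already embedded graph with the same table adds
    nothing new, because targets only ever link to gene-kind nodes.
    ``evidence`` restricts the table to ``low_throughput`` pairs when set.
    """
    g = nx.Graph()
    base = pathway.graph
    for node, attrs in base.nodes(data=True):
        kind = attrs.get("kind", GENE)
        g.add_node(node, **{**attrs, "kind": kind})
    g.add_edges_from(base.edges(data=True))
    gene_nodes = {n for n, k in g.nodes(data="kind") if k == GENE}

    table = targets.filter_evidence(evidence)
    display = table.display_ids()
    for norm_id, gene_targets in sorted(table.targets_by_mirna().items()):
        contained = sorted(gene_targets & gene_nodes)
        if not contained:
            continue
        mirna = display[norm_id]
        g.add_node(mirna, kind=MIRNA)
        for gene in contained:
            g.add_edge(mirna, gene)
    return UPEM(pathway.pathway_id, pathway.name, g)


def strip_mirnas(upem: UPEM) -> PathwayGraph:
    """Remove all miRNA nodes, recovering the original pathway graph."""
    g = upem.graph.copy()
    g.remove_nodes_from([n for n, k in upem.graph.nodes(data="kind") if k == MIRNA])
    return PathwayGraph(upem.pathway_id, upem.name, g)


@dataclass(frozen=True)
class BackgroundCounts:
    """Genome-wide totals used as the enrichment background."""

    m_genes: int
    m_mirnas: int

    def __post_init__(self) -> None:
        if self.m_genes < 0 or self.m_mirnas < 0:
            raise ValueError("background counts must be non-negative")

    @property
    def total(self) -> int:
        return self.m_genes + self.m_mirnas


def build_background(
    upems: list[UPEM], genome_genes: int, genome_mirnas: int
) -> BackgroundCounts:
    """Record genome totals; they must cover every molecule seen in a UPEM."""
    bg = BackgroundCounts(genome_genes, genome_mirnas)
    seen = set()
    for u in upems:
        seen |= set(u.graph.nodes)
    if bg.total < len(seen):
        raise ValueError(
            f"background total {bg.total} smaller than {len(seen)} distinct UPEM molecules"
        )
    return bg
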