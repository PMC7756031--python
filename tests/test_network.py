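"""CMGN assembly, anticorrelation marking and topology statistics."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirsubpath.io import GENE, MIRNA, ExpressionMatrix
from mirsubpath.mining import Subpathway
from mirsubpath.network import (
    fit_degree_powerlaw,
    mark_anticorrelation,
    merge_network,
    topology_stats,
)

from .oracles import betweenness_oracle


def _subpathway(pid, edges, kinds=None):
    g = nx.Graph(edges)
    for n in g.nodes:
        g.nodes[n]["kind"] = (kinds or {}).get(n, GENE)
    return Subpathway(pid, pid.split("_")[0], pid, frozenset(g.nodes), g)


def test_merge_single_and_disjoint():
    sp1 = _subpathway("p1_1", [("a", "b"), ("b", "c")])
    merged = merge_network([sp1])
    assert set(merged.nodes) == {"a", "b", "c"}
    assert {frozenset(e) for e in merged.edges} == {frozenset(e) for e in sp1.graph.edges}
    sp2 = _subpathway("p2_1", [("x", "y")])
    both = merge_network([sp1, sp2])
    assert both.number_of_nodes() == 5 and both.number_of_edges() == 3


def test_merge_inclusion_exclusion_and_order_independence():
    rng = np.random.default_rng(31)
    for _ in range(20):
        g1 = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
        g2 = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
        g2 = nx.relabel_nodes(g2, {i: i + 6 for i in g2.nodes})  # overlap on 6..11
        sp1 = _subpathway("p1_1", list(g1.edges))
        sp2 = _subpathway("p2_1", list(g2.edges))
        merged = merge_network([sp1, sp2])
        e1 = {frozenset(e) for e in g1.edges}
        e2 = {frozenset(e) for e in g2.edges}
        assert merged.number_of_edges() == len(e1) + len(e2) - len(e1 & e2)
        # order independence
        other = merge_network([sp2, sp1])
        assert nx.utils.graphs_equal(merged, other)
        # shared edges carry both origins
        for e in e1 & e2:
            a, b = tuple(e)
            assert merged.edges[a, b]["origins"] == ["p1_1", "p2_1"]


def _expr(rows: dict, samples, kind):
    df = pd.DataFrame(rows, index=samples).T
    return ExpressionMatrix(df, pd.Series(kind, index=df.index))


def test_anticorrelation_flags():
    samples = [f"s{i}" for i in range(6)]
    gene_profile = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    genes = _expr({"gA": gene_profile, "gB": gene_profile}, samples, GENE)
    mirnas = _expr({"miR-1": -gene_profile, "miR-2": gene_profile}, samples, MIRNA)
    g = nx.Graph()
    g.add_node("gA", kind=GENE)
    g.add_node("gB", kind=GENE)
    g.add_node("miR-1", kind=MIRNA)
    g.add_node("miR-2", kind=MIRNA)
    g.add_edges_from([("miR-1", "gA"), ("miR-2", "gB"), ("gA", "gB")])
    corr = mark_anticorrelation(g, genes, mirnas)
    by_pair = {(r.mirna_id, r.gene_id): r for r in corr.itertuples()}
    assert by_pair[("miR-1", "gA")].pearson_r == pytest.approx(-1.0)
    assert by_pair[("miR-1", "gA")].anticorrelated
    assert by_pair[("miR-2", "gB")].pearson_r == pytest.approx(1.0)
    assert not by_pair[("miR-2", "gB")].anticorrelated
    # gene-gene edge untouched
    assert "anticorrelated" not in g.edges["gA", "gB"]


def test_anticorrelation_affine_invariance_and_errors():
    samples = [f"s{i}" for i in range(5)]
    rng = np.random.default_rng(7)
    x = rng.normal(size=5)
    genes = _expr({"gA": x}, samples, GENE)
    g = nx.Graph()
    g.add_node("gA", kind=GENE)
    g.add_node("miR-1", kind=MIRNA)
    g.add_edge("miR-1", "gA")
    r_base = mark_anticorrelation(
        g, genes, _expr({"miR-1": -x}, samples, MIRNA)
    )["pearson_r"].iloc[0]
    r_affine = mark_anticorrelation(
        g, genes, _expr({"miR-1": 3.0 * (-x) + 10.0}, samples, MIRNA)
    )["pearson_r"].iloc[0]
    assert r_base == pytest.approx(r_affine)
    # zero variance -> unflagged, r undefined
    flat = _expr({"miR-1": np.zeros(5)}, samples, MIRNA)
    corr = mark_anticorrelation(g, genes, flat)
    assert not corr["anticorrelated"].iloc[0]
    assert np.isnan(corr["pearson_r"].iloc[0])
    # too few shared samples
    with pytest.raises(ValueError, match="shared samples"):
        mark_anticorrelation(
            g, genes, _expr({"miR-1": [1.0, 2.0]}, ["z1", "z2"], MIRNA)
        )


def test_planted_anticorrelated_pairs_flagged(fitted):
    assert fitted.recovery().get("anticorr_flag_rate", 0.0) >= 0.95


def test_star_graph_topology():
    g = nx.star_graph(5)  # center 0, leaves 1..5
    stats_df, _, _ = topology_stats(g)
    stats_df = stats_df.set_index("node_id")
    assert stats_df.loc[0, "degree"] == 5
    assert stats_df.loc[0, "betweenness"] == pytest.approx(1.0)
    assert (stats_df.drop(index=0)["betweenness"] == 0).all()
    assert stats_df["degree"].sum() == 2 * g.number_of_edges()


def test_exact_power_law_fit():
    # K1,3 has degree histogram {1: 3, 3: 1} -- exactly count = 3 * d^-1,
    # so the log-log regression must return slope -1 with R^2 = 1
    fit = fit_degree_powerlaw(nx.star_graph(3))
    assert fit.slope == pytest.approx(-1.0)
    assert fit.r_squared == pytest.approx(1.0)
    # degree-regular graphs have a single histogram point: fit undefined
    assert np.isnan(fit_degree_powerlaw(nx.cycle_graph(5)).slope)


def test_betweenness_matches_bruteforce_oracle():
    rng = np.random.default_rng(17)
    for seed in range(5):
        g = nx.gnp_random_graph(14, 0.25, seed=seed)
        stats_df, _, _ = topology_stats(g)
        expected = betweenness_oracle(g)
        got = dict(zip(stats_df["node_id"], stats_df["betweenness"]))
        for node, val in expected.items():
            assert got[node] == pytest.approx(val, abs=1e-10)


def test_group_comparison_known_vs_other():
    g = nx.barbell_graph(5, 2)
    known = [0, 1, 2]
    stats_df, _, comparison = topology_stats(g, known_nodes=known)
    assert set(comparison["metric"]) == {"degree", "betweenness"}
    row = comparison.set_index("metric").loc["degree"]
    sub = stats_df.set_index("node_id")
    assert row["known_mean"] == pytest.approx(sub.loc[known, "degree"].mean())
    assert np.isfinite(row["ranksum_p"])
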