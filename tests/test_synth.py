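"""Statistical structure and determinism of the synthetic-data generator."""

import dataclasses

import networkx as nx
import numpy as np
import pytest

from mirsubpath.survival import cox_univariate
from mirsubpath.synth import (
    SyntheticSpec,
    generate_all,
    generate_expression,
    generate_pathways,
    generate_survival,
    generate_targets,
    test_scale_spec as small_spec,
)


def test_full_determinism_under_seed():
    a = generate_all(small_spec(3))
    b = generate_all(small_spec(3))
    assert a.gene_expr.values.equals(b.gene_expr.values)
    assert a.mirna_expr.values.equals(b.mirna_expr.values)
    assert a.targets.pair_set() == b.targets.pair_set()
    assert a.survival.data.equals(b.survival.data)
    for pa, pb in zip(a.pathways, b.pathways):
        assert set(map(frozenset, pa.graph.edges)) == set(map(frozenset, pb.graph.edges))
    assert a.ground_truth.planted_subregions == b.ground_truth.planted_subregions


def test_planted_subregions_connected_and_recorded():
    pathways, gt = generate_pathways(small_spec(5))
    assert gt.planted_subregions
    graphs = {p.pathway_id: p.graph for p in pathways}
    for pid, region in gt.planted_subregions.items():
        assert len(region) >= 10
        assert nx.is_connected(graphs[pid].subgraph(region))
        assert nx.is_connected(graphs[pid])


def test_no_planting_gives_empty_ground_truth():
    spec = dataclasses.replace(small_spec(1), planted_subpathway_fraction=0.0,
                               anticorr_pairs=0)
    _, gt = generate_pathways(spec)
    assert gt.planted_subregions == {}
    assert gt.de_genes == [] and gt.de_mirnas == []


def test_spec_validation():
    with pytest.raises(ValueError, match="pathway_size_range"):
        generate_pathways(dataclasses.replace(small_spec(1), pathway_size_range=(2, 5)))
    with pytest.raises(ValueError, match="n_genes"):
        SyntheticSpec(n_genes=0).validate()
    with pytest.raises(ValueError, match="at least 3"):
        spec = dataclasses.replace(small_spec(1), n_case=2)
        pw, gt = generate_pathways(dataclasses.replace(spec, n_case=20))
        generate_expression(spec, pw, gt)


def test_null_effect_gives_no_group_shift():
    spec = dataclasses.replace(small_spec(2), de_effect=0.0)
    pathways, gt = generate_pathways(spec)
    gene_expr, _, labels = generate_expression(spec, pathways, gt)
    case = gene_expr.values[labels.case_samples].to_numpy()
    ctrl = gene_expr.values[labels.control_samples].to_numpy()
    diffs = case.mean(axis=1) - ctrl.mean(axis=1)
    se = spec.noise_sd * np.sqrt(1 / spec.n_case + 1 / spec.n_control) / np.sqrt(len(diffs))
    assert abs(diffs.mean()) < 3 * se


def test_planted_effect_gives_large_t_statistics():
    """Monte-Carlo power check: planted genes have two-sample t >> 5."""
    from scipy import stats

    hits = total = 0
    for seed in range(5):
        spec = small_spec(seed)  # de_effect=2, noise_sd=0.5, 20+20
        pathways, gt = generate_pathways(spec)
        gene_expr, _, labels = generate_expression(spec, pathways, gt)
        case = gene_expr.values.loc[gt.de_genes, labels.case_samples].to_numpy()
        ctrl = gene_expr.values.loc[gt.de_genes, labels.control_samples].to_numpy()
        t = stats.ttest_ind(case, ctrl, axis=1).statistic
        hits += int((t > 5).sum())
        total += len(t)
    assert hits / total > 0.99


def test_anticorrelated_pairs_are_strongly_negative():
    bundle = generate_all(small_spec(4))
    for mirna, gene in bundle.ground_truth.anticorr_pairs:
        r = np.corrcoef(
            bundle.mirna_expr.values.loc[mirna], bundle.gene_expr.values.loc[gene]
        )[0, 1]
        assert r < -0.9


def test_targets_density_and_planted_pairs():
    # density 0: only the planted anticorrelated targets remain
    spec = dataclasses.replace(small_spec(6), target_density=0.0)
    pathways, gt = generate_pathways(spec)
    table = generate_targets(spec, pathways, gt)
    planted = {
        (m, g) for m, targets in gt.anticorr_targets.items() for g in targets
    }
    assert table.pair_set() == planted
    # mean out-degree tracks the Poisson rate (no planted extras)
    spec2 = dataclasses.replace(
        SyntheticSpec(n_genes=200, n_mirnas=150, target_density=3.0, anticorr_pairs=0,
                      seed=8)
    )
    pathways2, gt2 = generate_pathways(spec2)
    table2 = generate_targets(spec2, pathways2, gt2)
    # duplicates collapse, so compare against the deduplicated expectation loosely
    mean_deg = len(table2) / spec2.n_mirnas
    se = np.sqrt(spec2.target_density / spec2.n_mirnas)
    assert abs(mean_deg - spec2.target_density) < 3 * se + 0.2


def test_survival_censoring_and_errors(bundle):
    spec = dataclasses.replace(bundle.spec, censor_rate=0.0)
    surv = generate_survival(spec, bundle.gene_expr, bundle.ground_truth.prognostic)
    assert (surv.data["event"] == 1).all()
    with pytest.raises(ValueError, match="absent"):
        generate_survival(spec, bundle.gene_expr, ["not_a_gene"])


def test_survival_beta_sign_recovery():
    """Strong planted hazard coefficient is recovered in sign by Cox."""
    recovered = 0
    reps = 20
    for seed in range(reps):
        spec = SyntheticSpec(n_genes=20, n_mirnas=5, n_case=100, n_control=100,
                             n_pathways=2, survival_beta=1.5, n_prognostic=1,
                             seed=seed)
        bundle = generate_all(spec)
        mol = bundle.ground_truth.prognostic[0]
        fit = cox_univariate(bundle.gene_expr.row(mol), bundle.survival, mol)
        if fit.converged and fit.b > 0:
            recovered += 1
    assert recovered >= int(0.95 * reps)
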