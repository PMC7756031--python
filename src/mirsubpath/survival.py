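"""Risk-score survival evaluation of network modules.

Per-molecule univariate Cox proportional-hazards coefficients (Efron tie
handling) weight a per-sample linear risk score
``Riskscore = sum_i b_i * Exp(i)``; the cohort is split at the median risk
score (ties to the low group) and the two arms are compared by a
Kaplan-Meier estimate with a two-tailed log-rank test (chi-square, 1 df).
A module may also be screened exhaustively: every non-empty subset of its
coding genes is re-fitted and ranked by log-rank p to find the most
compact prognostic signature.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test

from .io import GENE, ExpressionMatrix, SurvivalTable

logger = logging.getLogger(__name__)

HIGH = "high"
LOW = "low"


@dataclass(frozen=True)
class CoxFit:
    molecule_id: str
    b: float
    se: float
    converged: bool


def cox_univariate(values: pd.Series, surv: SurvivalTable,
                   molecule_id: str = "x") -> CoxFit:
    """Univariate Cox PH fit of survival on one molecule's expression.

    ``values`` is indexed by sample id; only samples present in both the
    series and the survival table are used.  Monotone-likelihood /
    non-convergent fits are reported with ``converged=False``.
    """
    shared = [s for s in surv.sample_ids if s in values.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 samples shared with the survival table")
    x = values.loc[shared].to_numpy(dtype=float)
    if float(np.var(x)) == 0.0:
        raise ValueError(f"zero-variance covariate for molecule {molecule_id!r}")
    sub = surv.data.loc[shared]
    if int(sub["event"].sum()) < 2:
        raise ValueError("need at least 2 observed events")
    df = pd.DataFrame(
        {"time": sub["time_months"].to_numpy(), "event": sub["event"].to_numpy(), "x": x}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="time", event_col="event")
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    except ConvergenceError:
        return CoxFit(molecule_id, float("nan"), float("nan"), False)
    b = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not (np.isfinite(b) and np.isfinite(se)):
        converged = False
    return CoxFit(molecule_id, b, se, converged)


@dataclass
class RiskModel:
    """Cox-weighted risk scores and the median-split group assignment."""

    coefficients: dict[str, float]
    scores: pd.Series
    cutoff: float
    groups: pd.Series  # sample -> 'high' | 'low'
    dropped: list[str] = field(default_factory=list)

    @property
    def high_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == HIGH])

    @property
    def low_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == LOW])


def risk_scores(
    molecules: list[str] | set[str],
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    min_present: float = 0.6,
    coefficients: dict[str, float] | None = None,
) -> RiskModel:
    """Per-sample risk score over a molecule set, median-split into groups.

    Coefficients come from per-molecule univariate Cox fits on the same
    cohort unless given explicitly; non-converged molecules are dropped
    (logged).  Samples strictly above the median score are 'high', the rest
    'low'.  A degenerate split (all scores identical) raises.
    """
    molecules = sorted(set(molecules))
    present = [m for m in molecules if m in set(expr.molecule_ids)]
    if not present:
        raise ValueError("no module molecule present in the expression matrix")
    frac = len(present) / len(molecules)
    if frac < min_present:
        warnings.warn(
            f"only {frac:.0%} of module molecules matched the expression profile "
            f"(threshold {min_present:.0%})",
            stacklevel=2,
        )
    shared = [s for s in surv.sample_ids if s in set(expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 samples shared between expression and survival")
    sub_surv = surv.subset(shared)

    coeffs: dict[str, float] = {}
    dropped: list[str] = []
    for mol in present:
        if coefficients is not None:
            coeffs[mol] = coefficients[mol]
            continue
        try:
            fit = cox_univariate(expr.row(mol), sub_surv, molecule_id=mol)
        except ValueError:
            dropped.append(mol)
            continue
        if fit.converged:
            coeffs[mol] = fit.b
        else:
            dropped.append(mol)
    if dropped:
        logger.info("dropped %d non-converged/degenerate molecules: %s", len(dropped), dropped)
    if not coeffs:
        raise ValueError("no molecule yielded a converged Cox coefficient")

    b = np.array([coeffs[m] for m in sorted(coeffs)])
    X = expr.values.loc[sorted(coeffs), shared].to_numpy(dtype=float)
    scores = pd.Series(b @ X, index=shared, name="riskscore")
    cutoff = float(scores.median())
    if float(scores.max()) == float(scores.min()):
        raise ValueError("degenerate risk split: all risk scores identical")
    groups = pd.Series(np.where(scores > cutoff, HIGH, LOW), index=scores.index)
    return RiskModel(coefficients=coeffs, scores=scores, cutoff=cutoff,
                     groups=groups, dropped=dropped)


@dataclass
class KMResult:
    """Kaplan-Meier curves per group plus the two-group log-rank test."""

    curves: dict[str, pd.DataFrame]
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("log-rank p-value must be in (0, 1]")


def km_logrank(surv: SurvivalTable, groups: pd.Series | dict) -> KMResult:
    """Product-limit curves and the two-tailed log-rank test for two arms."""
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    data = surv.data.loc[groups.index]
    if int(data["event"].sum()) == 0:
        raise ValueError("no observed events; log-rank test undefined")
    arms = {}
    for label in labels:
        ids = groups.index[groups == label]
        if len(ids) == 0:
            raise ValueError(f"group {label!r} is empty")
        arms[label] = data.loc[ids]
    res = logrank_test(
        arms[labels[0]]["time_months"],
        arms[labels[1]]["time_months"],
        event_observed_A=arms[labels[0]]["event"],
        event_observed_B=arms[labels[1]]["event"],
    )
    curves = {}
    for label in labels:
        kmf = KaplanMeierFitter()
        kmf.fit(arms[label]["time_months"], arms[label]["event"], label=str(label))
        sf = kmf.survival_function_
        curves[label] = sf.rename(columns={sf.columns[0]: "survival"})
    p = float(res.p_value)
    return KMResult(curves=curves, statistic=float(res.test_statistic),
                    p_value=min(max(p, np.nextafter(0, 1)), 1.0))


def single_gene_split(gene: str, expr: ExpressionMatrix, surv: SurvivalTable) -> KMResult:
    """Median split on one gene's expression (above median -> high), then KM."""
    shared = [s for s in surv.sample_ids if s in set(expr.sample_ids)]
    values = expr.row(gene).loc[shared]
    cutoff = float(values.median())
    groups = pd.Series(np.where(values > cutoff, HIGH, LOW), index=values.index)
    if groups.nunique() < 2:
        raise ValueError(f"median split of {gene!r} leaves one group empty")
    return km_logrank(surv.subset(shared), groups)


def module_km(
    molecules: list[str] | set[str],
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    min_present: float = 0.6,
) -> tuple[RiskModel, KMResult]:
    """Risk-score model plus KM/log-rank for a module's molecule set."""
    model = risk_scores(molecules, expr, surv, min_present=min_present)
    km = km_logrank(surv.subset(list(model.groups.index)), model.groups)
    return model, km


def best_signature_search(
    molecules: list[str],
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    max_subset_size: int | None = None,
    kinds: dict[str, str] | None = None,
    genes_only: bool = True,
    max_combinations: int = 10_000_000,
) -> pd.DataFrame:
    """Exhaustive combination search over a module's coding genes.

    Every non-empty subset (optionally bounded in size) is re-fitted with
    the risk-score model and ranked by log-rank p ascending, ties broken by
    fewer molecules then lexicographic ids.  Subsets whose fit fails
    (degenerate split, no converged coefficient) are recorded with p = NaN.
    """
    pool = sorted(set(molecules) & set(expr.molecule_ids))
    if genes_only:
        kind_of = kinds or {}
        pool = [m for m in pool if kind_of.get(m, GENE) == GENE]
    if not pool:
        raise ValueError("no searchable molecules present in the expression matrix")
    max_size = min(max_subset_size or len(pool), len(pool))
    n_combos = sum(math.comb(len(pool), r) for r in range(1, max_size + 1))
    if n_combos > max_combinations:
        raise ValueError(
            f"{n_combos} subsets exceed the limit {max_combinations}; "
            "set max_subset_size to bound the search"
        )
    rows = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(pool, size):
            try:
                _, km = module_km(list(combo), expr, surv, min_present=0.0)
                p = km.p_value
            except ValueError:
                p = float("nan")
            rows.append({"molecules": combo, "n_molecules": size, "logrank_p": p})
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["logrank_p", "n_molecules", "molecules"],
        key=lambda col: col if col.name != "molecules" else col.map(lambda t: tuple(t)),
        na_position="last",
    ).reset_index(drop=True)
    return df


def module_vs_gene_report(
    molecules: list[str],
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    mirna_expr: ExpressionMatrix | None = None,
    kinds: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Whole-module log-rank p next to every single-gene p.

    The first row is the whole module (coding genes; genes+miRNAs when a
    miRNA matrix is supplied), flagged ``better_than_any_gene`` when its p
    beats the best single coding gene.
    """
    kind_of = kinds or {m: GENE for m in molecules}
    genes = [m for m in sorted(set(molecules)) if kind_of.get(m, GENE) == GENE]
    search_expr = expr
    module_molecules: list[str] = list(genes)
    if mirna_expr is not None:
        from .io import concat_expression

        search_expr = concat_expression(expr, mirna_expr)
        module_molecules = sorted(set(molecules))
    try:
        _, module_result = module_km(module_molecules, search_expr, surv, min_present=0.0)
        module_p = module_result.p_value
    except ValueError:
        module_p = float("nan")
    rows = [{"unit": "module", "ids": tuple(module_molecules), "logrank_p": module_p,
             "better_than_any_gene": False}]
    gene_ps = []
    for gene in genes:
        if gene not in set(expr.molecule_ids):
            continue
        try:
            res = single_gene_split(gene, expr, surv)
            p = res.p_value
        except ValueError:
            p = float("nan")
        gene_ps.append(p)
        rows.append({"unit": "gene", "ids": (gene,), "logrank_p": p,
                     "better_than_any_gene": False})
    finite = [p for p in gene_ps if np.isfinite(p)]
    if finite and np.isfinite(module_p):
        rows[0]["better_than_any_gene"] = bool(module_p < min(finite))
    return pd.DataFrame(rows)
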