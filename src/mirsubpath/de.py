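"""Two-class differential expression with a SAM-style relative-difference
statistic and a permutation-estimated false discovery rate.

The statistic for molecule i is ``d_i = (mean_case - mean_control) / (s_i + s0)``
where ``s_i`` is the pooled two-sample standard-error term and ``s0`` is a
small fudge factor (default: the 5th percentile of the ``s_i``) that damps
the inflation of d for molecules with tiny variance.  The FDR is estimated
by permuting group labels: for each candidate threshold on ``|d|``, the FDR
is the median permuted exceedance count over the observed exceedance count,
and a molecule's q-value is the minimum FDR over thresholds at or below its
own ``|d|``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConditionLabels, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureSet:
    """Differentially expressed molecule sets used as signature nodes."""

    de_genes: frozenset[str]
    de_mirnas: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.de_genes & self.de_mirnas
        if overlap:
            raise ValueError(f"molecule in both gene and miRNA sets: {sorted(overlap)[0]!r}")

    @property
    def all_nodes(self) -> frozenset[str]:
        return self.de_genes | self.de_mirnas

    def __len__(self) -> int:
        return len(self.de_genes) + len(self.de_mirnas)


def _case_control_arrays(
    matrix: ExpressionMatrix, labels: ConditionLabels
) -> tuple[np.ndarray, int, int]:
    labels.validate_against(matrix)
    case = labels.case_samples
    ctrl = labels.control_samples
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("each condition needs at least 2 samples")
    arr = matrix.values[case + ctrl].to_numpy(dtype=float)
    return arr, len(case), len(ctrl)


def _d_stat(arr: np.ndarray, mask: np.ndarray, n1: int, n2: int,
            s0: float | None) -> tuple[np.ndarray, np.ndarray, float]:
    """d, s_i and the s0 actually used, for a boolean case-column mask."""
    case = arr[:, mask]
    ctrl = arr[:, ~mask]
    num = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    pooled_var = ss / (n1 + n2 - 2)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled_var)
    if s0 is None:
        s0 = float(np.percentile(s, 5))
    denom = s + s0
    d = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    return d, s, s0


def sam_statistic(
    matrix: ExpressionMatrix,
    labels: ConditionLabels,
    s0: float | None = None,
) -> pd.Series:
    """Per-molecule SAM d statistic (case minus control).

    ``s0=None`` uses the 5th percentile of the per-molecule standard errors;
    ``s0=0`` reduces d to the ordinary two-sample t form.
    """
    arr, n1, n2 = _case_control_arrays(matrix, labels)
    mask = np.zeros(n1 + n2, dtype=bool)
    mask[:n1] = True
    d, _, used_s0 = _d_stat(arr, mask, n1, n2, s0)
    logger.debug("sam_statistic: s0=%.6g", used_s0)
    return pd.Series(d, index=matrix.values.index, name="d_stat")


def _label_masks(n: int, n1: int, n_perm: int, seed: int) -> np.ndarray:
    """Distinct case/control reassignments preserving group sizes.

    Enumerates all C(n, n1) assignments when feasible (seed-independent),
    otherwise samples distinct assignments without replacement.
    """
    total = math.comb(n, n1)
    if total <= n_perm:
        logger.info("only %d distinct label permutations; enumerating all", total)
        masks = np.zeros((total, n), dtype=bool)
        for row, combo in enumerate(itertools.combinations(range(n), n1)):
            masks[row, list(combo)] = True
        return masks
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    rows: list[tuple[int, ...]] = []
    while len(rows) < n_perm:
        combo = tuple(sorted(map(int, rng.choice(n, size=n1, replace=False))))
        if combo not in seen:
            seen.add(combo)
            rows.append(combo)
    masks = np.zeros((n_perm, n), dtype=bool)
    for row, combo in enumerate(rows):
        masks[row, list(combo)] = True
    return masks


def permutation_fdr(
    matrix: ExpressionMatrix,
    labels: ConditionLabels,
    n_perm: int = 100,
    seed: int = 0,
    s0: float | None = None,
) -> pd.Series:
    """Permutation q-value per molecule (clipped to [0, 1], monotone in |d|)."""
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    arr, n1, n2 = _case_control_arrays(matrix, labels)
    n = n1 + n2
    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[:n1] = True
    d_obs, _, used_s0 = _d_stat(arr, obs_mask, n1, n2, s0)
    abs_obs = np.abs(d_obs)
    thresholds = np.sort(abs_obs)  # ascending candidate thresholds
    n_mol = len(thresholds)
    # observed exceedance count at each threshold (ties handled by searchsorted)
    obs_count = n_mol - np.searchsorted(thresholds, thresholds, side="left")

    masks = _label_masks(n, n1, n_perm, seed)
    perm_counts = np.empty((len(masks), n_mol), dtype=np.int64)
    for p, mask in enumerate(masks):
        d_perm, _, _ = _d_stat(arr, mask, n1, n2, used_s0)
        abs_perm = np.sort(np.abs(d_perm))
        perm_counts[p] = n_mol - np.searchsorted(abs_perm, thresholds, side="left")
    med = np.median(perm_counts, axis=0)
    fdr = np.clip(med / obs_count, 0.0, 1.0)
    # q = min FDR over thresholds at or below each molecule's |d|
    prefix_min = np.minimum.accumulate(fdr)
    q = prefix_min[np.searchsorted(thresholds, abs_obs, side="left")]
    return pd.Series(q, index=matrix.values.index, name="q_value")


def differential_expression(
    matrix: ExpressionMatrix,
    labels: ConditionLabels,
    fdr_threshold: float,
    n_perm: int = 100,
    seed: int = 0,
    s0: float | None = None,
) -> pd.DataFrame:
    """d statistic, q-value and signature call for every molecule."""
    d = sam_statistic(matrix, labels, s0=s0)
    q = permutation_fdr(matrix, labels, n_perm=n_perm, seed=seed, s0=s0)
    return pd.DataFrame(
        {
            "molecule_id": matrix.values.index,
            "d_stat": d.to_numpy(),
            "q_value": q.to_numpy(),
            "is_signature": (q < fdr_threshold).to_numpy(),
        }
    ).set_index("molecule_id", drop=False)


def build_signature(
    gene_de: pd.DataFrame,
    mirna_de: pd.DataFrame,
    gene_fdr: float = 0.001,
    mirna_fdr: float = 0.05,
) -> SignatureSet:
    """Molecules passing their kind-specific FDR threshold."""
    genes = frozenset(gene_de.index[gene_de["q_value"] < gene_fdr])
    mirnas = frozenset(mirna_de.index[mirna_de["q_value"] < mirna_fdr])
    return SignatureSet(de_genes=genes, de_mirnas=mirnas)


def signature_from_lists(de_genes, de_mirnas) -> SignatureSet:
    """Accept externally computed DE lists directly (bypass route)."""
    return SignatureSet(frozenset(de_genes), frozenset(de_mirnas))
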