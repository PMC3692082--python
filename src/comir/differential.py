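"""Comparisons between prediction runs: differences, thresholds, rank-sum tests.

Because the ComiR score depends on the miRNA expression profile, the same
miRNA list scored under two samples (or two groups of replicate samples)
yields different per-gene probabilities.  This module computes per-gene
score differences between two labels, filters non-targets by a score
threshold, and — for two groups of at least three samples each — runs a
per-gene two-sided Wilcoxon rank-sum test to find the "differentially
predicted" genes.  The exact null distribution (with midranks for ties)
is enumerated for small groups; larger groups use the tie-corrected
normal approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, norm, rankdata

from .svm import ComirResult, rank_normalize

__all__ = [
    "GroupComparison",
    "score_difference",
    "rank_sum_test",
    "wilcoxon_differential",
    "filter_targets",
]

#: Groups no larger than this use the exact enumerated null.
EXACT_MAX_GROUP = 8


@dataclass(frozen=True)
class GroupComparison:
    """Specification of a two-group comparison over result labels."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    use_ranks: bool = False
    bh_correction: bool = False

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if len(a) != len(self.group_a) or len(b) != len(self.group_b):
            raise ValueError("duplicate sample labels within a group")
        if a & b:
            raise ValueError(f"groups overlap: {sorted(a & b)}")
        if len(a) < 3 or len(b) < 3:
            raise ValueError("each group needs at least 3 samples")


def score_difference(result: ComirResult, label_a: str, label_b: str) -> pd.Series:
    """Per-gene difference score(a) - score(b) between two labels."""
    for label in (label_a, label_b):
        if label not in result.probabilities.columns:
            raise KeyError(f"unknown label {label!r}")
    diff = result.probabilities[label_a] - result.probabilities[label_b]
    return diff.rename(f"diff_{label_a}_vs_{label_b}")


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two small-to-moderate samples.

    Uses midranks for ties.  When min(n, m) <= EXACT_MAX_GROUP the p-value
    is computed from the exact permutation null (every C(n+m, n) labeling
    of the pooled values), which remains valid under ties; otherwise the
    normal approximation with tie-corrected variance and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    if min(n, m) <= EXACT_MAX_GROUP and comb(n + m, n) <= 50_000:
        dev = abs(w_obs - mu)
        hits = 0
        total = 0
        for idx in combinations(range(n + m), n):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                hits += 1
        return hits / total
    # Normal approximation with tie correction and continuity correction.
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (N * (N - 1)))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))


def wilcoxon_differential(
    result: ComirResult, comparison: GroupComparison
) -> pd.DataFrame:
    """Per-gene rank-sum test between two groups of samples.

    Returns a frame indexed by gene with columns ``p_value`` and
    ``mean_difference`` (mean of group A minus mean of group B).  With
    ``use_ranks`` the comparison runs on each sample's fractional ranks of
    the probabilities instead of the probabilities themselves, making it
    invariant to monotone rescaling within a sample.  ``bh_correction``
    appends a Benjamini-Hochberg ``q_value`` column.
    """
    labels = set(result.probabilities.columns)
    missing = (set(comparison.group_a) | set(comparison.group_b)) - labels
    if missing:
        raise KeyError(f"unknown sample label(s): {sorted(missing)}")
    values = result.probabilities
    if comparison.use_ranks:
        values = pd.DataFrame(
            {c: rank_normalize(values[c], "higher_is_target") for c in values.columns},
            index=values.index,
        )
    a = values.loc[:, list(comparison.group_a)].to_numpy()
    b = values.loc[:, list(comparison.group_b)].to_numpy()
    p_values = np.array(
        [rank_sum_test(a[k], b[k]) for k in range(values.shape[0])]
    )
    out = pd.DataFrame(
        {
            "p_value": p_values,
            "mean_difference": a.mean(axis=1) - b.mean(axis=1),
        },
        index=values.index,
    )
    if comparison.bh_correction:
        out["q_value"] = false_discovery_control(p_values, method="bh")
    return out


def filter_targets(
    result: ComirResult, threshold: float, drop_nontargets: bool = True
) -> ComirResult:
    """Drop genes not predicted as a target under any label.

    A gene is kept iff its maximum score over all labels reaches the
    threshold; with ``drop_nontargets`` unset this is the identity.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if not drop_nontargets:
        return result
    keep = result.probabilities.max(axis=1) >= threshold
    return ComirResult(
        probabilities=result.probabilities.loc[keep],
        ranks=None if result.ranks is None else result.ranks.loc[keep],
        extra=None if result.extra is None else result.extra.loc[keep],
    )
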