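"""Virtual sorting: in-silico partition of samples by a source gene.

Samples are split into source-high and source-low groups by the exact
two-cluster solution of the one-dimensional k-means objective on the source
gene's percentile-rank scores.  Optimal 1-D clusters are contiguous in
sorted order, so the global optimum is found by an exhaustive scan over the
n-1 contiguous split points — deterministic, no initialization, no seed.

For every gene the screen then computes

    delta = ARS(source-high samples) - ARS(source-low samples)

(the delta_ARS statistic, in [-100, 100]).  Strongly negative delta marks
candidate mutual exclusion with the source; strongly positive delta marks
co-existing expression.  Significance per gene is a two-sided Wilcoxon
rank-sum test on the percentile-rank scores between groups, corrected
across all genes of one source-gene screen with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .plasticity import RankMatrix

#: default minimum samples per group; ARS and the rank-sum test are
#: unstable below this
DEFAULT_MIN_GROUP = 10

#: maximum combined group size at which the tie-free Wilcoxon null is
#: enumerated exactly rather than normal-approximated
EXACT_WILCOXON_MAX_N = 25


class ZeroPlasticityError(ValueError):
    """The source gene's rank vector is constant: ME analysis impossible."""


@dataclass(frozen=True)
class GroupAssignment:
    """A two-group labelling of samples by source-gene rank score."""

    source_gene: str
    labels: pd.Series  # per-sample "high"/"low"
    boundary: float  # rank-score threshold separating the groups
    n_high: int
    n_low: int

    @property
    def high_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "high"])

    @property
    def low_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "low"])


def _split_costs(sorted_vals: np.ndarray) -> np.ndarray:
    """Within-cluster sum of squares for every contiguous split of a sorted vector.

    Entry k is the WCSS of {v[:k]} vs {v[k:]}, k = 1..n-1, computed with
    prefix sums in O(n).
    """
    n = sorted_vals.size
    c1 = np.cumsum(sorted_vals)
    c2 = np.cumsum(sorted_vals**2)
    k = np.arange(1, n)
    left_ss = c2[k - 1] - c1[k - 1] ** 2 / k
    right_n = n - k
    right_sum = c1[-1] - c1[k - 1]
    right_sq = c2[-1] - c2[k - 1]
    right_ss = right_sq - right_sum**2 / right_n
    return left_ss + right_ss


def partition_samples(r: RankMatrix, source: str, min_group: int = DEFAULT_MIN_GROUP) -> GroupAssignment:
    """Split samples into source-high / source-low by exact 1-D 2-means.

    The cluster with the larger mean is "high".  Samples tied exactly at
    the boundary value always land on the same side (labels are a function
    of the rank value alone, not of sample order).

    Raises
    ------
    ZeroPlasticityError
        If the source gene's rank vector is constant.
    ValueError
        If the source is absent or a group ends up smaller than `min_group`.
    """
    if source not in r.data.index:
        raise ValueError(f"source gene {source!r} not present in the matrix")
    vals = r.data.loc[source].to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise ZeroPlasticityError(
            f"source gene {source!r} has zero plasticity (constant rank scores); ME analysis impossible"
        )
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    costs = _split_costs(sorted_vals)
    # splits inside a run of ties are not value-definable; mask them out
    valid = sorted_vals[1:] > sorted_vals[:-1]
    costs = np.where(valid, costs, np.inf)
    k = int(np.argmin(costs)) + 1
    boundary = (sorted_vals[k - 1] + sorted_vals[k]) / 2.0
    labels = pd.Series(np.where(vals > boundary, "high", "low"), index=r.data.columns, name="group")
    n_high = int((labels == "high").sum())
    n_low = int((labels == "low").sum())
    if n_high < min_group or n_low < min_group:
        raise ValueError(
            f"partition of {source!r} gives groups high={n_high}, low={n_low}; "
            f"both must have at least min_group={min_group} samples"
        )
    return GroupAssignment(source_gene=source, labels=labels, boundary=float(boundary), n_high=n_high, n_low=n_low)


def delta_ars(r: RankMatrix, g: GroupAssignment) -> pd.DataFrame:
    """Per-gene ARS in each group and their difference delta = high - low."""
    high = r.data[g.high_samples].mean(axis=1)
    low = r.data[g.low_samples].mean(axis=1)
    return pd.DataFrame({"ars_high": high, "ars_low": low, "delta": high - low})


def rank_sum_test(values_high: np.ndarray, values_low: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for one gene.

    Uses the exact null distribution when the combined sample size is at
    most 25 and there are no ties; otherwise the normal approximation with
    tie and continuity corrections.  Identical constant groups give p = 1.
    """
    x = np.asarray(values_high, dtype=float)
    y = np.asarray(values_low, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires two non-empty groups")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    total = x.size + y.size
    tie_free = np.unique(pooled).size == total
    method = "exact" if (total <= EXACT_WILCOXON_MAX_N and tie_free) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_test_matrix(high: np.ndarray, low: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for a genes x samples split."""
    total = high.shape[1] + low.shape[1]
    if total <= EXACT_WILCOXON_MAX_N:
        return np.array([rank_sum_test(high[i], low[i]) for i in range(high.shape[0])])
    p = mannwhitneyu(high, low, alternative="two-sided", method="asymptotic", axis=1).pvalue
    # rows constant across both groups have zero rank variance -> define p = 1
    flat = (np.ptp(high, axis=1) == 0) & (np.ptp(low, axis=1) == 0) & (high[:, 0] == low[:, 0])
    p = np.where(flat, 1.0, p)
    return np.clip(p, 0.0, 1.0)


def virtual_sort(r: RankMatrix, source: str, min_group: int = DEFAULT_MIN_GROUP) -> pd.DataFrame:
    """Run one source gene's virtual-sorting screen over all genes.

    Composes the partition, per-gene delta_ARS, the per-gene rank-sum test
    on rank scores, and BH correction across all genes of the screen.

    Returns a DataFrame indexed by gene, sorted by delta descending, with
    columns ``ars_high, ars_low, delta, p_raw, p_adj``; the source gene's
    own row is included (its delta is positive by construction).
    """
    g = partition_samples(r, source, min_group=min_group)
    table = delta_ars(r, g)
    values = r.values
    high_idx = [r.data.columns.get_loc(s) for s in g.high_samples]
    low_idx = [r.data.columns.get_loc(s) for s in g.low_samples]
    p_raw = _rank_sum_test_matrix(values[:, high_idx], values[:, low_idx])
    table["p_raw"] = p_raw
    table["p_adj"] = adjust_bh(p_raw)
    table = table.sort_values("delta", ascending=False, kind="stable")
    table.index.name = "gene_id"
    table.attrs["source_gene"] = source
    table.attrs["n_high"] = g.n_high
    table.attrs["n_low"] = g.n_low
    table.attrs["boundary"] = g.boundary
    return table


def volcano_table(sorting: pd.DataFrame) -> pd.DataFrame:
    """Delta-volcano export: per-gene delta vs -log10 adjusted p."""
    with np.errstate(divide="ignore"):
        neg_log = -np.log10(sorting["p_adj"].to_numpy())
    return pd.DataFrame({"delta": sorting["delta"], "neg_log10_p_adj": neg_log}, index=sorting.index)
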