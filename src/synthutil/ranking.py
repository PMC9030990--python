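"""Rank-based validation statistics: H/M/L grouping, the exact Page trend
test, and footrule rank aggregation.

For each utility metric, the three synthesizers are grouped per dataset as
H (smallest metric value — highest predicted utility), M and L.  Each
group member is replaced by its workload difference (AUROC or AUPRC) and
the three values are ranked within the dataset's row.  With column rank
sums R1, R2, R3 over (H, M, L), the Page statistic is

    L = R1 + 2*R2 + 3*R3,

large when workload differences increase from H to L, i.e. when the metric
ranks methods the way the workload does.  Significance uses the exact null
distribution of L (each row an independent uniform permutation of ranks
1..3), with a Bonferroni adjustment across the metrics tested.  An
aggregate ranking per dataset minimizes the total Spearman footrule
distance to the individual metric rankings over all 3! candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import permutations

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "RankMatrix",
    "PageTestResult",
    "AggregateRanking",
    "assign_groups",
    "build_rank_matrix",
    "page_l",
    "page_null_distribution",
    "page_exact_pvalue",
    "monte_carlo_pvalue",
    "page_test",
    "bonferroni",
    "footrule",
    "aggregate_ranking",
]

# L contribution of a single row (weights 1,2,3 over the 6 permutations of
# ranks 1..3): {10: 1, 11: 2, 13: 2, 14: 1} out of 6
_ROW_COUNTS = {10: 1, 11: 2, 13: 2, 14: 1}


@dataclass
class RankMatrix:
    """Datasets x (H, M, L): within-row ranks of workload differences."""

    ranks: np.ndarray  # shape (n, 3); each row a permutation of 1..3 (or mid-ranks)
    dataset_names: list[str] = field(default_factory=list)
    workload_name: str = ""
    metric_name: str = ""
    has_ties: bool = False

    @property
    def n_rows(self) -> int:
        return self.ranks.shape[0]

    def validate(self) -> None:
        r = np.asarray(self.ranks, dtype=float)
        if r.ndim != 2 or r.shape[1] != 3:
            raise ValueError("rank matrix must be n x 3")
        if not np.allclose(r.sum(axis=1), 6.0):
            raise ValueError("each row must hold ranks summing to 6")


@dataclass
class PageTestResult:
    L: float
    n_rows: int
    p_value: float
    significant: bool
    alpha_adjusted: float
    exact: bool = True
    metric_name: str = ""
    workload_name: str = ""


@dataclass
class AggregateRanking:
    """Footrule-optimal consensus over per-metric method rankings."""

    ranking: dict[str, int]  # method -> rank (1 best)
    total_cost: float
    tie_broken: bool = False


# ----------------------------------------------------------------------
# Grouping
# ----------------------------------------------------------------------

def assign_groups(metric_means: dict[str, float]) -> tuple[tuple[str, str, str], bool]:
    """Order three methods into (H, M, L) by a distance-type metric.

    H gets the smallest value (highest utility), L the largest.  Ties are
    broken lexicographically by method name; the second return value flags
    whether a tie occurred.
    """
    if len(metric_means) != 3:
        raise ValueError("grouping requires exactly 3 methods")
    items = sorted(metric_means.items(), key=lambda kv: (kv[1], kv[0]))
    vals = [v for _, v in items]
    ties = len(set(vals)) < 3
    return (items[0][0], items[1][0], items[2][0]), ties


def build_rank_matrix(
    groups_per_dataset: dict[str, tuple[str, str, str]],
    diffs_per_dataset: dict[str, dict[str, float]],
    workload_name: str = "",
    metric_name: str = "",
) -> RankMatrix:
    """Replace each (H, M, L) group member by its workload difference and
    rank within rows (smallest difference -> rank 1; ties -> mid-ranks,
    flagged)."""
    names = sorted(groups_per_dataset)
    rows = []
    has_ties = False
    for name in names:
        if name not in diffs_per_dataset:
            raise ValueError(f"missing workload differences for dataset {name!r}")
        order = groups_per_dataset[name]
        diffs = [diffs_per_dataset[name][m] for m in order]
        r = rankdata(diffs, method="average")
        if len(set(diffs)) < 3:
            has_ties = True
        rows.append(r)
    rm = RankMatrix(
        ranks=np.array(rows, dtype=float),
        dataset_names=names,
        workload_name=workload_name,
        metric_name=metric_name,
        has_ties=has_ties,
    )
    rm.validate()
    return rm


# ----------------------------------------------------------------------
# Page statistic and exact null
# ----------------------------------------------------------------------

def page_l(rm: RankMatrix) -> float:
    """L = R1 + 2*R2 + 3*R3 over the (H, M, L) column rank sums."""
    rm.validate()
    col_sums = rm.ranks.sum(axis=0)
    L = float(col_sums @ np.array([1.0, 2.0, 3.0]))
    return L


def page_null_distribution(n_rows: int) -> dict[int, int]:
    """Exact null counts of L over all 6^n rank matrices, by dynamic-
    programming convolution of the per-row contribution distribution."""
    if n_rows < 1:
        raise ValueError("need n_rows >= 1")
    dist = {0: 1}
    for _ in range(n_rows):
        new: dict[int, int] = {}
        for tot, cnt in dist.items():
            for contrib, c in _ROW_COUNTS.items():
                new[tot + contrib] = new.get(tot + contrib, 0) + cnt * c
        dist = new
    return dist


def page_exact_pvalue(l_obs: float, n_rows: int) -> Fraction:
    """Exact upper-tail p-value P(L >= l_obs) under the uniform-permutation
    null, as an exact rational number.  Requires a tie-free matrix (integer
    ranks); mid-rank matrices go through :func:`monte_carlo_pvalue`."""
    dist = page_null_distribution(n_rows)
    total = 6 ** n_rows
    tail = sum(c for v, c in dist.items() if v >= l_obs - 1e-9)
    return Fraction(tail, total)


def monte_carlo_pvalue(rm: RankMatrix, reps: int = 100_000, seed: int = 0) -> float:
    """Permutation p-value: independently permute each row's rank values
    ``reps`` times; p = (1 + #{L* >= L_obs}) / (reps + 1).  Valid with
    mid-ranks, where the closed-form null does not apply."""
    rng = np.random.default_rng(seed)
    l_obs = page_l(rm)
    ranks = rm.ranks
    n = rm.n_rows
    w = np.array([1.0, 2.0, 3.0])
    count = 0
    # vectorized: for each rep draw a permutation per row
    perms = np.array(list(permutations(range(3))))
    for _ in range(reps):
        idx = rng.integers(0, 6, size=n)
        permuted = np.take_along_axis(ranks, perms[idx], axis=1)
        if permuted.sum(axis=0) @ w >= l_obs - 1e-9:
            count += 1
    return (1 + count) / (reps + 1)


def page_test(rm: RankMatrix, alpha: float = 0.05, m: int = 1,
              mc_reps: int = 100_000, mc_seed: int = 0) -> PageTestResult:
    """Page trend test with Bonferroni-adjusted decision.

    Tie-free matrices get the exact p-value; matrices with mid-ranks fall
    back to the row-permutation Monte-Carlo null (flagged via ``exact``).
    """
    l_obs = page_l(rm)
    tie_free = np.allclose(rm.ranks, np.round(rm.ranks)) and not rm.has_ties
    if tie_free:
        p = float(page_exact_pvalue(l_obs, rm.n_rows))
        exact = True
    else:
        p = monte_carlo_pvalue(rm, reps=mc_reps, seed=mc_seed)
        exact = False
    alpha_adj = alpha / m
    return PageTestResult(
        L=l_obs, n_rows=rm.n_rows, p_value=p,
        significant=p < alpha_adj, alpha_adjusted=alpha_adj, exact=exact,
        metric_name=rm.metric_name, workload_name=rm.workload_name,
    )


def bonferroni(p_values: list[float], alpha: float = 0.05,
               m: int | None = None) -> list[bool]:
    """Significance decisions at the Bonferroni-adjusted level alpha/m."""
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    return [p < alpha / m for p in p_values]


# ----------------------------------------------------------------------
# Footrule aggregation
# ----------------------------------------------------------------------

def footrule(r1, r2) -> float:
    """Spearman footrule distance sum_i |r1(i) - r2(i)|."""
    a = np.asarray(r1, dtype=float)
    b = np.asarray(r2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rankings differ in length")
    return float(np.abs(a - b).sum())


def aggregate_ranking(per_metric_rankings: list[dict[str, int]]) -> AggregateRanking:
    """Footrule-median consensus over the 3 methods by full enumeration.

    All 3! candidate rankings are scored by total footrule distance to the
    inputs.  Cost ties are broken by majority pairwise preference (a method
    ranked above another in most inputs stays above), then lexicographically
    by method name; any tie-break is flagged.
    """
    if not per_metric_rankings:
        raise ValueError("need at least one input ranking")
    methods = sorted(per_metric_rankings[0])
    for r in per_metric_rankings:
        if sorted(r) != methods:
            raise ValueError("rankings cover different method sets")
    if len(methods) != 3:
        raise ValueError("aggregation is defined over exactly 3 methods")

    # majority pairwise preference: pref[a][b] = #inputs ranking a above b
    pref = {a: {b: 0 for b in methods} for a in methods}
    for r in per_metric_rankings:
        for a in methods:
            for b in methods:
                if a != b and r[a] < r[b]:
                    pref[a][b] += 1

    scored = []
    for perm in permutations(methods):
        cand = {m: i + 1 for i, m in enumerate(perm)}
        cost = sum(
            footrule([r[m] for m in methods], [cand[m] for m in methods])
            for r in per_metric_rankings
        )
        majority = sum(
            1 for a in methods for b in methods
            if a != b and cand[a] < cand[b] and pref[a][b] > pref[b][a]
        )
        scored.append(((cost, -majority, perm), cand))
    scored.sort(key=lambda t: t[0])
    min_cost = scored[0][0][0]
    tie = sum(1 for k, _ in scored if abs(k[0] - min_cost) < 1e-12) > 1
    return AggregateRanking(ranking=scored[0][1], total_cost=min_cost,
                            tie_broken=tie)
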