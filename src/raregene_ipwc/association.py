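"""Partition-trait association statistics and multiplicity handling.

Three statistics connect a trait vector y to a partition of the n
individuals into k elements of sizes n_i:

* the partition-retention influence measure

      I = sum_i n_i^2 (ybar_i - ybar)^2 / (n s^2),

  where ybar_i is the element mean, ybar and s the overall mean and
  (population, denominator-n) standard deviation. Under the null, I
  converges to a weighted sum of 1-df chi-squares; its exact null mean for
  i.i.d. traits is 1 - sum_i n_i^2 / n^2, which tends to 1 as the largest
  element share tends to 0. I is affine-invariant in y and applies to both
  quantitative and dichotomous traits. It is used with a rank-based
  top-fraction selection rule rather than a p-value.
* one-way ANOVA (asymptotic F p-value),
* Pearson's chi-square test of independence on the 2 x k table of a
  dichotomous trait against the partition (df = k - 1, no continuity
  correction).

A Fisher exact test for 2 x c tables (probability-mass two-sided
definition, direct enumeration over the margin-consistent tables) is
provided for diagnostics of sparse partition-SNP cross tables. Selection is
by Bonferroni on p-values or by retaining the top fraction of genes ranked
by statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .datamodel import DICHOTOMOUS, TraitVector
from .partitioning import Partition

__all__ = [
    "PartitionRetentionResult",
    "TestResult",
    "SelectionRule",
    "partition_retention_i",
    "null_expected_i",
    "anova_test",
    "chisq_test",
    "chisq_from_table",
    "fisher_exact_rxc",
    "apply_selection",
    "permutation_pvalue",
]


@dataclass
class PartitionRetentionResult:
    i_score: float
    element_means: np.ndarray
    overall_mean: float
    overall_sd: float
    sizes: np.ndarray
    n: int
    degenerate: bool = False


@dataclass
class TestResult:
    """One statistic for one (gene, trait, method, k) combination."""

    method: str
    statistic: float
    p_value: Optional[float] = None
    df: Optional[tuple] = None
    gene: str = ""
    trait: str = ""
    k: Optional[int] = None
    flags: Set[str] = field(default_factory=set)
    selected: Optional[bool] = None


@dataclass
class SelectionRule:
    """Bonferroni on p-values, or top-fraction ranking on the statistic."""

    mode: str
    alpha: float = 0.05
    fraction: float = 0.001

    def __post_init__(self) -> None:
        if self.mode not in ("bonferroni", "top_fraction"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode == "top_fraction" and not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        if self.mode == "bonferroni" and not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def _check_lengths(y: TraitVector, part: Partition) -> None:
    if len(y) != part.n:
        raise ValueError(
            f"trait length {len(y)} does not match partition over {part.n}"
        )


def _group_means(values: np.ndarray, part: Partition) -> np.ndarray:
    sums = np.bincount(part.labels, weights=values, minlength=part.k + 1)[1:]
    return sums / part.sizes


def partition_retention_i(y: TraitVector, part: Partition) -> PartitionRetentionResult:
    """Partition-retention influence I between a trait and a partition.

    Works identically for quantitative and 0/1 traits. A constant trait
    (s = 0) yields I = 0 with the degenerate flag set.
    """
    _check_lengths(y, part)
    values = y.values
    n = part.n
    ybar = float(values.mean())
    s2 = float(values.var())  # population (denominator n) variance
    means = _group_means(values, part)
    if s2 == 0.0:
        return PartitionRetentionResult(
            i_score=0.0, element_means=means, overall_mean=ybar,
            overall_sd=0.0, sizes=part.sizes, n=n, degenerate=True,
        )
    num = float(np.sum(part.sizes.astype(float) ** 2 * (means - ybar) ** 2))
    return PartitionRetentionResult(
        i_score=num / (n * s2), element_means=means, overall_mean=ybar,
        overall_sd=math.sqrt(s2), sizes=part.sizes, n=n,
    )


def null_expected_i(part: Partition) -> float:
    """Exact null mean of I for i.i.d. traits: 1 - sum n_i^2 / n^2."""
    n = float(part.n)
    return 1.0 - float(np.sum((part.sizes / n) ** 2))


def anova_test(y: TraitVector, part: Partition) -> TestResult:
    """Classical one-way F test of equal element means.

    Dichotomous traits are treated as numeric 0/1. Zero pooled within-group
    variance with unequal means gives F = inf, p = 0 and a flag.
    """
    _check_lengths(y, part)
    if part.k < 2:
        raise ValueError("ANOVA needs at least 2 partition elements")
    values = y.values
    n, k = part.n, part.k
    if n <= k:
        raise ValueError("ANOVA needs n > k for within-group df")
    grand = values.mean()
    means = _group_means(values, part)
    ss_between = float(np.sum(part.sizes * (means - grand) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_within = max(ss_total - ss_between, 0.0)
    df = (k - 1, n - k)
    flags: Set[str] = set()
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult("anova", 0.0, 1.0, df, trait=y.name, k=k,
                              flags={"degenerate"})
        flags.add("zero_within_variance")
        return TestResult("anova", float("inf"), 0.0, df, trait=y.name, k=k,
                          flags=flags)
    f = (ss_between / df[0]) / (ss_within / df[1])
    p = float(stats.f.sf(f, df[0], df[1]))
    return TestResult("anova", f, p, df, trait=y.name, k=k, flags=flags)


def chisq_from_table(table: np.ndarray) -> TestResult:
    """Pearson chi-square of independence on an r x c count table.

    No continuity correction; df = (r-1)(c-1). A zero row or column margin
    makes the statistic 0 with p = 1 and a degenerate flag. Any expected
    count below 5 (Cochran's rule) raises the 'sparse' flag warning that
    the asymptotic p-value is unreliable (statistic still computed).
    """
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    flags: Set[str] = set()
    df = ((table.shape[0] - 1) * (table.shape[1] - 1),)
    if np.any(rows == 0) or np.any(cols == 0):
        return TestResult("chisq", 0.0, 1.0, df, flags={"degenerate"})
    expected = np.outer(rows, cols) / n
    if np.any(expected < 5.0):
        flags.add("sparse")
    stat = float(np.sum((table - expected) ** 2 / expected))
    p = float(stats.chi2.sf(stat, df[0]))
    return TestResult("chisq", stat, p, df, flags=flags)


def chisq_test(y: TraitVector, part: Partition) -> TestResult:
    """Chi-square independence test of a 0/1 trait against the partition."""
    _check_lengths(y, part)
    if y.kind != DICHOTOMOUS:
        raise ValueError("chi-square test requires a dichotomous trait")
    if part.k < 2:
        raise ValueError("chi-square test needs at least 2 elements")
    yi = y.values.astype(int)
    table = np.zeros((2, part.k))
    for row in (0, 1):
        table[row] = np.bincount(
            part.labels[yi == row], minlength=part.k + 1
        )[1:]
    res = chisq_from_table(table)
    res.trait, res.k = y.name, part.k
    return res


def fisher_exact_rxc(table: Sequence[Sequence[int]]) -> TestResult:
    """Exact two-sided Fisher test for a 2 x c contingency table.

    The p-value sums the multivariate hypergeometric probabilities of every
    table with the observed margins whose probability does not exceed that
    of the observed table (probability-mass ordering, the convention of the
    classical network algorithm). Enumeration is direct over the first row,
    column by column, with log-gamma arithmetic; suitable for the sparse
    2 x c tables met in partition diagnostics.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise ValueError("table must be 2 x c with c >= 2")
    if np.any(obs < 0):
        raise ValueError("table entries must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("all margins must be positive")
    n = int(obs.sum())
    r = int(rows[0])
    c = obs.shape[1]

    def log_comb(m: np.ndarray, x: np.ndarray) -> np.ndarray:
        return gammaln(m + 1) - gammaln(x + 1) - gammaln(m - x + 1)

    log_denom = float(log_comb(np.array(n), np.array(r)))
    logp_obs = float(np.sum(log_comb(cols, obs[0]))) - log_denom
    # tolerance mirrors the usual exact-test practice of treating tables
    # whose probability ties the observed one (up to rounding) as extreme
    cutoff = logp_obs + 1e-7

    suffix_cap = np.concatenate([np.cumsum(cols[::-1])[::-1][1:], [0]])
    total = 0.0
    p_two = 0.0

    def recurse(j: int, remaining: int, partial: float) -> None:
        nonlocal total, p_two
        if j == c - 1:
            lp = partial + float(log_comb(cols[j], np.array(remaining))) - log_denom
            pr = math.exp(lp)
            total += pr
            if lp <= cutoff:
                p_two += pr
            return
        lo = max(0, remaining - int(suffix_cap[j]))
        hi = min(int(cols[j]), remaining)
        if j == c - 2:
            a = np.arange(lo, hi + 1)
            b = remaining - a
            valid = b <= cols[j + 1]
            a = a[valid]
            b = b[valid]
            lp = (
                partial
                + log_comb(np.full_like(a, cols[j]), a)
                + log_comb(np.full_like(b, cols[j + 1]), b)
                - log_denom
            )
            pr = np.exp(lp)
            total += float(pr.sum())
            p_two += float(pr[lp <= cutoff].sum())
            return
        for a in range(lo, hi + 1):
            recurse(
                j + 1,
                remaining - a,
                partial + float(log_comb(np.array(cols[j]), np.array(a))),
            )

    recurse(0, r, 0.0)
    # `total` sums to 1 over all margin-consistent tables; guard rounding
    p = min(p_two / total, 1.0)
    return TestResult("fisher", math.exp(logp_obs), p, df=obs.shape)


def apply_selection(
    results: Iterable[TestResult], rule: SelectionRule
) -> Set[str]:
    """Select genes from one screen's per-gene results.

    Bonferroni: genes with p <= alpha / n_tests where n_tests is the number
    of results. Top-fraction: rank by statistic descending, keep
    ceil(fraction * n_genes); ties broken by statistic then gene id.
    The ``selected`` flag is set on every result.
    """
    results = list(results)
    if not results:
        return set()
    if rule.mode == "bonferroni":
        threshold = rule.alpha / len(results)
        chosen = set()
        for res in results:
            if res.p_value is None:
                raise ValueError(
                    f"result for {res.gene!r} has no p-value; Bonferroni "
                    "selection needs p-values"
                )
            res.selected = res.p_value <= threshold
            if res.selected:
                chosen.add(res.gene)
        return chosen
    n_keep = math.ceil(rule.fraction * len(results))
    ranked = sorted(results, key=lambda res: (-res.statistic, res.gene))
    chosen = {res.gene for res in ranked[:n_keep]}
    for res in results:
        res.selected = res.gene in chosen
    return chosen


def permutation_pvalue(
    y: TraitVector,
    part: Partition,
    statistic: str = "partition_retention",
    n_permutations: int = 999,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Permutation p-value for any of the three statistics.

    Trait values are permuted across individuals; p = (1 + #{perm >= obs})
    / (1 + B).
    """
    rng = rng or np.random.default_rng()

    def stat(vec: TraitVector) -> float:
        if statistic == "partition_retention":
            return partition_retention_i(vec, part).i_score
        if statistic == "anova":
            return anova_test(vec, part).statistic
        if statistic == "chisq":
            return chisq_test(vec, part).statistic
        raise ValueError(f"unknown statistic {statistic!r}")

    obs = stat(y)
    count = 0
    for _ in range(n_permutations):
        perm = TraitVector(rng.permutation(y.values), kind=y.kind, name=y.name)
        if stat(perm) >= obs:
            count += 1
    return (1 + count) / (1 + n_permutations)
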