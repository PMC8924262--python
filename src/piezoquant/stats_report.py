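"""Responder and neurite statistics.

The centrepiece is an exact two-sided Fisher test on 2x2 responder tables
using the sum-of-small-p convention: the two-sided p-value is the sum of the
hypergeometric point probabilities of every margin-preserving table whose
point probability does not exceed that of the observed table (near-ties
within a relative tolerance of 1e-7 count as ties).  The implementation
works in exact integer arithmetic on binomial coefficients, so tie
comparisons are exact.

Also here: percentage summaries of x/n proportions (nearest integer, half
away from zero), per-group neurite summaries (percent neurite-bearing,
mean +/- SEM of the longest neurite over neurite-bearing cells, cumulative
neurite-count distribution), and a normality-gated group comparison that
dispatches to parametric (t / one-way ANOVA + Dunnett) or nonparametric
(Mann-Whitney / Kruskal-Wallis + Dunn) routines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidParameterError, WindowError

TIE_RTOL = 1e-7


@dataclass(frozen=True)
class CountsTable2x2:
    """Responder counts: (a, b) = group-1 responders/non-responders,
    (c, d) = group-2 responders/non-responders."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise InvalidParameterError("counts must be non-negative integers")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise InvalidParameterError("row sums must be > 0")

    @classmethod
    def from_responders(cls, x1: int, n1: int, x2: int, n2: int) -> "CountsTable2x2":
        """Build from responder fractions x1/n1 and x2/n2."""
        return cls(x1, n1 - x1, x2, n2 - x2)


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    odds_ratio: float  # sample odds ratio (a*d)/(b*c)
    degenerate: bool = False


def fisher_exact_2x2(table: CountsTable2x2) -> FisherResult:
    """Two-sided Fisher exact test, sum-of-small-p convention.

    Sums hypergeometric point probabilities over all tables with the
    observed margins whose probability is <= the observed one, treating
    probabilities within a relative tolerance of 1e-7 as tied.  Implemented
    with exact integer binomial coefficients; only the final ratio is
    floating point.  A zero row or column margin yields p = 1 by convention,
    flagged degenerate.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    k = a + c  # first-column margin
    n = r1 + r2
    if k == 0 or k == n:
        odds = _sample_odds_ratio(a, b, c, d)
        return FisherResult(1.0, odds, degenerate=True)

    # point "probability" numerators: C(r1, a') * C(r2, k - a'); the common
    # denominator C(n, k) cancels from all comparisons
    lo, hi = max(0, k - r2), min(r1, k)
    observed = comb(r1, a) * comb(r2, k - a)
    # exact tie comparison: num <= observed * (1 + 1e-7), in integers
    scale = 10**9
    bound = observed * (scale + int(TIE_RTOL * scale))
    total = 0
    for a_prime in range(lo, hi + 1):
        num = comb(r1, a_prime) * comb(r2, k - a_prime)
        if num * scale <= bound:
            total += num
    p = total / comb(n, k)
    return FisherResult(min(1.0, p), _sample_odds_ratio(a, b, c, d))


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


@dataclass(frozen=True)
class ProportionResult:
    """A proportion both exactly and as an integer percentage."""

    percent_exact: float
    percent_rounded: int
    x: int
    n: int


def proportion_percent(x: int, n: int) -> ProportionResult:
    """100*x/n, exact and rounded to the nearest integer (half away from 0)."""
    if n <= 0:
        raise InvalidParameterError("n must be > 0")
    if not (0 <= x <= n):
        raise InvalidParameterError("require 0 <= x <= n")
    exact = 100.0 * x / n
    rounded = int(math.floor(exact + 0.5))
    return ProportionResult(exact, rounded, x, n)


@dataclass(frozen=True)
class NeuriteGroupSummary:
    group: str
    n_cells: int
    n_neurite_bearing: int
    percent_bearing: ProportionResult
    mean_longest: float  # µm, over neurite-bearing cells; NaN if none
    sem_longest: float
    cumulative_n_neurites: pd.Series  # P(N <= k) over all cells
    empty_lengths: bool = False


def summarize_neurites(table: pd.DataFrame) -> dict[str, NeuriteGroupSummary]:
    """Per-group neurite summaries.

    ``table`` needs columns group, longest_neurite, n_neurites (and
    optionally neurite_bearing; otherwise inferred as n_neurites >= 1).
    Length statistics (mean +/- SEM, SEM = sd/sqrt(N)) are computed over
    neurite-bearing cells only; the cumulative neurite-count distribution is
    over all cells of the group.
    """
    if len(table) == 0:
        raise WindowError("empty neurite table")
    df = table.copy()
    if "neurite_bearing" not in df:
        df["neurite_bearing"] = df["n_neurites"] >= 1
    out: dict[str, NeuriteGroupSummary] = {}
    for group, sub in df.groupby("group", sort=False):
        if len(sub) == 0:
            raise WindowError(f"empty group {group!r}")
        bearing = sub[sub["neurite_bearing"]]
        n_bear = len(bearing)
        if n_bear:
            lengths = bearing["longest_neurite"].to_numpy(dtype=float)
            mean = float(lengths.mean())
            sem = float(lengths.std(ddof=1) / math.sqrt(n_bear)) if n_bear > 1 else float("nan")
            empty = False
        else:
            mean = sem = float("nan")
            empty = True
        counts = sub["n_neurites"].to_numpy()
        ks = np.arange(0, counts.max() + 1 if len(counts) else 1)
        cumulative = pd.Series(
            [(counts <= k).mean() for k in ks], index=ks, name="cumulative"
        )
        out[str(group)] = NeuriteGroupSummary(
            group=str(group),
            n_cells=len(sub),
            n_neurite_bearing=n_bear,
            percent_bearing=proportion_percent(n_bear, len(sub)),
            mean_longest=mean,
            sem_longest=sem,
            cumulative_n_neurites=cumulative,
            empty_lengths=empty,
        )
    return out


@dataclass(frozen=True)
class GroupComparisonResult:
    """Uniform contract for two- or k-group location comparisons."""

    test_name: str
    statistic: float
    p_value: float
    parametric: bool
    posthoc: list[tuple[str, str, float, float]] = field(default_factory=list)
    normality_p: dict[str, float] = field(default_factory=dict)


def _dunn_posthoc(
    values_by_group: dict[str, np.ndarray], control: str | None
) -> list[tuple[str, str, float, float]]:
    """Dunn's rank-based z tests after Kruskal-Wallis, with tie correction.

    No multiplicity adjustment is applied beyond the z statistics unless the
    caller adjusts downstream (the adjustment convention is configurable by
    post-processing the returned raw p-values).
    """
    names = list(values_by_group)
    pooled = np.concatenate([values_by_group[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        k = values_by_group[g].size
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    pairs = (
        [(control, g) for g in names if g != control]
        if control is not None
        else [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    )
    out = []
    for g1, g2 in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out.append((g1, g2, float(z), float(p)))
    return out


MIN_N_NORMALITY = 8  # the omnibus normality test needs >= 8 observations


def group_compare(
    values_by_group: dict[str, list[float] | np.ndarray],
    control: str | None = None,
    alpha_normality: float = 0.05,
) -> GroupComparisonResult:
    """Normality-gated two- or k-group comparison.

    Every group is screened with the D'Agostino-Pearson omnibus test; if all
    pass at ``alpha_normality`` (and have enough observations for the test),
    the parametric branch is used (Student's t for two groups, one-way ANOVA
    with Dunnett's post test against ``control`` for more); otherwise the
    nonparametric branch (Mann-Whitney U, or Kruskal-Wallis with Dunn's post
    test).  Post-hoc comparisons are returned as (group1, group2,
    statistic, p) tuples.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise WindowError("need >= 2 groups")
    for g, v in groups.items():
        if v.size < 3:
            raise WindowError(f"group {g!r} has fewer than 3 values")
    names = list(groups)

    normality_p: dict[str, float] = {}
    all_normal = True
    for g, v in groups.items():
        if v.size < MIN_N_NORMALITY or np.ptp(v) == 0:
            all_normal = False
            normality_p[g] = float("nan")
            continue
        p = float(stats.normaltest(v).pvalue)
        normality_p[g] = p
        if p < alpha_normality:
            all_normal = False

    if len(groups) == 2:
        v1, v2 = groups[names[0]], groups[names[1]]
        if all_normal:
            res = stats.ttest_ind(v1, v2)
            return GroupComparisonResult(
                "Student t", float(res.statistic), float(res.pvalue),
                True, normality_p=normality_p,
            )
        res = stats.mannwhitneyu(v1, v2, alternative="two-sided")
        return GroupComparisonResult(
            "Mann-Whitney U", float(res.statistic), float(res.pvalue),
            False, normality_p=normality_p,
        )

    if all_normal:
        res = stats.f_oneway(*groups.values())
        posthoc: list[tuple[str, str, float, float]] = []
        if control is not None:
            treat = [g for g in names if g != control]
            dres = stats.dunnett(
                *[groups[g] for g in treat], control=groups[control]
            )
            posthoc = [
                (control, g, float(s), float(p))
                for g, s, p in zip(treat, dres.statistic, dres.pvalue)
            ]
        return GroupComparisonResult(
            "one-way ANOVA + Dunnett", float(res.statistic), float(res.pvalue),
            True, posthoc=posthoc, normality_p=normality_p,
        )
    res = stats.kruskal(*groups.values())
    posthoc = _dunn_posthoc(groups, control)
    return GroupComparisonResult(
        "Kruskal-Wallis + Dunn", float(res.statistic), float(res.pvalue),
        False, posthoc=posthoc, normality_p=normality_p,
    )
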