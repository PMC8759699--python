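"""Cohort statistics: the study's nonparametric comparison plan.

Descriptives are median and IQR (25th-75th percentile, linear interpolation
of order statistics).  Between-group endpoint contrasts use the two-sided
Mann-Whitney U test (exact null distribution for small tie-free samples,
normal approximation with tie and continuity corrections otherwise).
Within-group time courses are compared to the time-0 baseline with
Friedman's test followed by Dunn's z comparisons against baseline,
Bonferroni-adjusted over the k-1 baseline contrasts only.  AUC endpoints,
which are treated as normally distributed, use the pooled-variance two-sample
t test with per-group t-based 95% confidence intervals.  Spearman rank
correlation uses an exact permutation p-value for n < 10 and the
t-approximation otherwise.  No correction is applied across distinct
endpoints; every comparison carries its raw two-sided p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

#: Largest combined sample for which the exact Mann-Whitney null is used.
MW_EXACT_MAX_N = 25
#: Largest n for which Spearman p is an exact permutation value.
SPEARMAN_EXACT_MAX_N = 9


@dataclass
class GroupSummary:
    label: str
    n: int
    center: float                 # median (rank tests) or mean (t test)
    low: float                    # q25 or CI lower bound
    high: float                   # q75 or CI upper bound
    kind: str = "median_iqr"      # or "mean_ci95"


@dataclass
class CohortComparison:
    endpoint: str
    statistic_name: str           # "U" | "t" | "Q" | "rho" | "z"
    statistic: float
    p_value: float
    df: float | None = None
    group_summaries: list[GroupSummary] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q25, q75) with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("median_iqr of an empty sample")
    q25, med, q75 = np.percentile(v, [25.0, 50.0, 75.0])
    return float(med), float(q25), float(q75)


def _median_summary(label: str, v: np.ndarray) -> GroupSummary:
    med, q25, q75 = median_iqr(v)
    return GroupSummary(label, int(v.size), med, q25, q75, "median_iqr")


def mann_whitney_u(x, y, endpoint: str = "",
                   labels: tuple[str, str] = ("x", "y")) -> CohortComparison:
    """Two-sided Mann-Whitney U test between two independent samples.

    The exact null distribution is used when n_x + n_y <= 25 and the pooled
    sample is tie-free; otherwise the normal approximation with tie and
    continuity corrections.  The reported U is the statistic for the first
    sample.  Fully degenerate input (all values identical) yields p = 1 with
    a warning instead of an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both samples must be non-empty")
    warnings = []
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return CohortComparison(
            endpoint=endpoint, statistic_name="U",
            statistic=float(x.size * y.size / 2.0), p_value=1.0,
            group_summaries=[_median_summary(labels[0], x),
                             _median_summary(labels[1], y)],
            warnings=["all values identical; no separation"],
        )
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= MW_EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
        if has_ties:
            warnings.append("ties present; normal approximation with tie correction")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return CohortComparison(
        endpoint=endpoint, statistic_name="U", statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_summaries=[_median_summary(labels[0], x),
                         _median_summary(labels[1], y)],
        warnings=warnings,
    )


def students_t(x, y, endpoint: str = "",
               labels: tuple[str, str] = ("x", "y")) -> CohortComparison:
    """Pooled-variance two-sample t test with per-group mean and 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("t test needs >= 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValidationError("zero pooled variance; t statistic undefined")
    res = sps.ttest_ind(x, y, equal_var=True)
    df = x.size + y.size - 2

    def _mean_ci(label: str, v: np.ndarray) -> GroupSummary:
        m = float(np.mean(v))
        half = float(sps.t.ppf(0.975, v.size - 1) * np.std(v, ddof=1) / math.sqrt(v.size))
        return GroupSummary(label, int(v.size), m, m - half, m + half, "mean_ci95")

    return CohortComparison(
        endpoint=endpoint, statistic_name="t", statistic=float(res.statistic),
        p_value=float(res.pvalue), df=float(df),
        group_summaries=[_mean_ci(labels[0], x), _mean_ci(labels[1], y)],
    )


def spearman(x, y, endpoint: str = "") -> CohortComparison:
    """Spearman rank correlation with a two-sided p-value.

    For n < 10 the p-value is exact: the proportion of all n! pairings whose
    |rho| reaches the observed |rho|.  For n >= 10 the usual t-approximation
    on rho is used.  Ties receive average ranks in both branches.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("samples must be paired 1-D arrays")
    n = x.size
    if n < 3:
        raise ValidationError("Spearman correlation needs n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValidationError("zero rank variance; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_MAX_N:
        rxc = rx - rx.mean()
        rxc /= math.sqrt(float(rxc @ rxc))
        perms = np.array(list(permutations(ry)), dtype=float)
        pc = perms - perms.mean(axis=1, keepdims=True)
        norms = np.sqrt(np.einsum("ij,ij->i", pc, pc))
        rhos = (pc @ rxc) / norms
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return CohortComparison(endpoint=endpoint, statistic_name="rho",
                            statistic=rho, p_value=p, df=float(n - 2))


@dataclass
class DunnsResult:
    time_label: float
    mean_rank: float
    z: float
    p_adjusted: float
    significant: bool
    direction: int      # +1 above baseline, -1 below, 0 equal


@dataclass
class FriedmanDunnsReport:
    statistic: float            # Friedman chi-square Q
    p_value: float
    df: int
    n_subjects: int             # complete blocks used
    n_dropped: int              # incomplete blocks removed listwise
    baseline_label: float
    baseline_mean_rank: float
    dunns: list[DunnsResult] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def friedman_with_dunns(block_matrix, time_labels, baseline_index: int = 0,
                        alpha: float = 0.05) -> FriedmanDunnsReport:
    """Friedman test across times plus Dunn's post hoc against baseline.

    ``block_matrix`` is subjects x times; rows containing NaN are dropped
    listwise (counted).  Within-subject average ranks feed the Friedman
    chi-square; each non-baseline time is compared to the baseline column
    with Dunn's z = (Rbar_j - Rbar_0) / sqrt(k(k+1)/(6n)), two-sided normal
    p multiplied by the k-1 comparisons (Bonferroni), capped at 1.
    """
    m = np.asarray(block_matrix, dtype=float)
    labels = [float(t) for t in time_labels]
    if m.ndim != 2 or m.shape[1] != len(labels):
        raise ValidationError("block_matrix must be subjects x len(time_labels)")
    complete = ~np.any(np.isnan(m), axis=1)
    dropped = int(np.sum(~complete))
    m = m[complete]
    n, k = m.shape
    if k < 3:
        raise ValidationError("Friedman test needs >= 3 time points")
    if n < 2:
        raise ValidationError("Friedman test needs >= 2 complete subjects")

    warnings = []
    ranks = sps.rankdata(m, axis=1)
    mean_ranks = ranks.mean(axis=0)
    if np.all(m == m[:, [0]]):
        stat, p = 0.0, 1.0
        warnings.append("all subjects constant over time; statistic 0")
    else:
        stat, p = sps.friedmanchisquare(*[m[:, j] for j in range(k)])
        if not math.isfinite(stat):   # fully tied after correction
            stat, p = 0.0, 1.0
            warnings.append("tie correction degenerate; statistic set to 0")

    se = math.sqrt(k * (k + 1) / (6.0 * n))
    base_rank = mean_ranks[baseline_index]
    dunns = []
    for j in range(k):
        if j == baseline_index:
            continue
        z = (mean_ranks[j] - base_rank) / se
        p_adj = min(1.0, 2.0 * sps.norm.sf(abs(z)) * (k - 1))
        dunns.append(DunnsResult(
            time_label=labels[j], mean_rank=float(mean_ranks[j]), z=float(z),
            p_adjusted=float(p_adj), significant=bool(p_adj < alpha),
            direction=int(np.sign(mean_ranks[j] - base_rank)),
        ))
    return FriedmanDunnsReport(
        statistic=float(stat), p_value=float(p), df=k - 1, n_subjects=n,
        n_dropped=dropped, baseline_label=labels[baseline_index],
        baseline_mean_rank=float(base_rank), dunns=dunns, warnings=warnings,
    )
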