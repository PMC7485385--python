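"""Two-group and multi-group inference used throughout the analysis.

* Pooled-variance Student's t-test, from raw values or from published
  summary statistics (mean, SEM, n) — the latter lets printed group
  summaries be re-tested without the raw measurements.
* One-way ANOVA with Fisher's protected LSD post hoc: pairwise t-tests
  sharing the ANOVA's within-group mean square, with the "protection"
  recorded as a flag (pairwise p-values stay visible even when the
  omnibus test is not significant).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "TTestResult",
    "PairwiseResult",
    "AnovaResult",
    "ttest_from_summary",
    "ttest_raw",
    "anova_fisher_lsd",
]

POOLED = "pooled"
WELCH = "welch"


@dataclass(frozen=True)
class GroupSummary:
    """Published group summary: mean +/- SEM with sample size."""

    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if not (math.isfinite(self.sem) and self.sem >= 0):
            raise ValueError(f"group {self.label!r}: SEM must be finite and >= 0")

    @property
    def sd(self) -> float:
        """Sample standard deviation implied by the SEM."""
        return self.sem * math.sqrt(self.n)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    method: str  # POOLED | WELCH


@dataclass(frozen=True)
class PairwiseResult:
    labels: tuple[str, str]
    mean_difference: float
    t: float
    p: float
    significant: bool  # protected: requires omnibus p < alpha AND pairwise p < alpha


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    posthoc: tuple[PairwiseResult, ...]


def ttest_from_summary(
    a: GroupSummary, b: GroupSummary, method: str = POOLED
) -> TTestResult:
    """Two-sided two-sample t-test from summary statistics.

    Pooled (classical Student's) by default: with equal n this reduces to
    t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2) on n_a + n_b - 2
    degrees of freedom.
    """
    equal_var = method == POOLED
    if method not in (POOLED, WELCH):
        raise ValueError(f"unknown method {method!r}")
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sem**2, b.sem**2
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TTestResult(t=float(t), df=df, p=float(p), method=method)


def ttest_raw(
    x: Sequence[float], y: Sequence[float], method: str = POOLED
) -> TTestResult:
    """Two-sided two-sample t-test on raw values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if method not in (POOLED, WELCH):
        raise ValueError(f"unknown method {method!r}")
    equal_var = method == POOLED
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    df = float(res.df)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue), method=method)


def anova_fisher_lsd(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA with Fisher's protected LSD pairwise comparisons.

    Pairwise tests use the shared within-group mean square with
    ``df_within`` degrees of freedom.  Protection is a flag: a pair is
    marked significant only when both the omnibus and the pairwise
    p-value fall below ``alpha``; the pairwise p itself is always
    reported.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        data = [np.asarray(groups[lab], dtype=float) for lab in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(data))]
    if len(data) < 3:
        raise ValueError("ANOVA needs >= 3 groups; use a t-test for two")
    for lab, g in zip(labels, data):
        if len(g) < 2:
            raise ValueError(f"group {lab!r} needs n >= 2")

    k = len(data)
    ns = [len(g) for g in data]
    total_n = sum(ns)
    df_between = k - 1
    df_within = total_n - k
    ms_within = sum((len(g) - 1) * g.var(ddof=1) for g in data) / df_within

    F, p = stats.f_oneway(*data)
    F, p = float(F), float(p)
    if not math.isfinite(F):  # all groups constant and equal
        F, p = 0.0, 1.0
    omnibus_sig = p < alpha

    posthoc = []
    for (i, j) in itertools.combinations(range(k), 2):
        diff = float(data[i].mean() - data[j].mean())
        if ms_within == 0:
            t_ij = math.inf if diff != 0 else 0.0
            p_ij = 0.0 if diff != 0 else 1.0
        else:
            se = math.sqrt(ms_within * (1 / ns[i] + 1 / ns[j]))
            t_ij = diff / se
            p_ij = 2 * float(stats.t.sf(abs(t_ij), df_within))
        posthoc.append(
            PairwiseResult(
                labels=(labels[i], labels[j]),
                mean_difference=diff,
                t=t_ij,
                p=p_ij,
                significant=omnibus_sig and p_ij < alpha,
            )
        )
    return AnovaResult(
        F=F,
        df_between=df_between,
        df_within=df_within,
        p=p,
        ms_within=float(ms_within),
        posthoc=tuple(posthoc),
    )
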