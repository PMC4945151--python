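"""Statistical battery: pooled t, log-ratio ANOVA + Tukey, Pearson r.

The two-sample test is the pooled-variance Student's t (df = n1+n2-2),
matched by per-group mean ± s.e.m., t-quantile 95% CIs and pooled-SD
Cohen's d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "AnovaResult",
    "group_summary",
    "students_t_pooled",
    "anova_log_ratios",
    "pearson_r",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float
    ci_low: float
    ci_high: float

    def as_dict(self) -> dict:
        return {"n": self.n, "mean": self.mean, "sem": self.sem,
                "ci95": [self.ci_low, self.ci_high]}


def group_summary(values, confidence: float = 0.95) -> GroupSummary:
    """n, mean, s.e.m. (SD/sqrt(n)) and t-quantile CI of one sample.

    A single observation yields NaN s.e.m./CI (flagged via warning).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("need a 1-d sample with n >= 1")
    n = len(x)
    mean = float(x.mean())
    if n < 2:
        log.warning("single observation: s.e.m. and CI undefined")
        return GroupSummary(n, mean, float("nan"), float("nan"), float("nan"))
    sem = float(x.std(ddof=1) / np.sqrt(n))
    tq = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1))
    return GroupSummary(n, mean, sem, mean - tq * sem, mean + tq * sem)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    effect_size: float
    group_a: GroupSummary
    group_b: GroupSummary

    def as_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p": self.p_value,
                "cohens_d": self.effect_size,
                "group_a": self.group_a.as_dict(),
                "group_b": self.group_b.as_dict()}


def students_t_pooled(group_a, group_b) -> TestResult:
    """Two-sided pooled-variance two-sample Student's t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must be finite")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            raise ValueError("zero pooled variance with equal means: t undefined")
        t_stat = np.inf if a.mean() > b.mean() else -np.inf
        p = 0.0
        d = np.inf
    else:
        t_stat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
        d = (a.mean() - b.mean()) / np.sqrt(sp2)
    return TestResult(float(t_stat), float(df), float(p), float(d),
                      group_summary(a), group_summary(b))


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: list[dict] = field(default_factory=list)
    n_zeros_excluded: int = 0

    def as_dict(self) -> dict:
        return {"F": self.f_statistic, "df": [self.df_between, self.df_within],
                "p": self.p_value, "tukey": self.tukey,
                "n_zeros_excluded": self.n_zeros_excluded}


def anova_log_ratios(*groups) -> AnovaResult:
    """One-way ANOVA on natural-log ratios, with Tukey HSD post hoc.

    Zero (or negative) ratios are excluded before the log transform and
    their count is reported; every group must stay non-empty.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    logged = []
    n_zeros = 0
    for g in groups:
        x = np.asarray(g, dtype=float)
        if x.size == 0:
            raise ValueError("empty group")
        bad = x <= 0
        n_zeros += int(bad.sum())
        x = x[~bad]
        if x.size == 0:
            raise ValueError("group has no positive ratios after exclusion")
        logged.append(np.log(x))
    if n_zeros:
        log.warning("excluded %d non-positive ratios before log transform", n_zeros)
    f_stat, p = sps.f_oneway(*logged)
    k = len(logged)
    n_total = sum(len(x) for x in logged)
    tukey_res = sps.tukey_hsd(*logged)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            pairs.append({"groups": [i, j],
                          "statistic": float(tukey_res.statistic[i, j]),
                          "p": float(tukey_res.pvalue[i, j])})
    return AnovaResult(float(f_stat), k - 1, n_total - k, float(p), pairs, n_zeros)


def pearson_r(series_a, series_b) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need equal-length 1-d series with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant series: correlation undefined")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)
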