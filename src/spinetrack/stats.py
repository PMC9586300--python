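"""Statistical layer: group comparisons, post hoc tests, outlier policy.

Mirrors a conventional Prism-style workflow: equal-variance Student t tests
by default (Welch behind a flag), ordinary one-way ANOVA with Tukey HSD
post hoc, paired t for within-animal day comparisons, a two-sided Grubbs
test that may exclude at most one animal per cohort, and the rule that the
two sham arms are pooled when they do not differ at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSeries",
    "TestResult",
    "unpaired_t",
    "paired_t",
    "one_way_anova_tukey",
    "grubbs_exclude",
    "grubbs_critical_value",
    "pool_sham",
    "PoolingDecision",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSeries:
    """Per-animal values for one group (the dots of a summary figure).

    ``n_excluded`` records outliers already removed: the exclusion policy
    allows at most one per cohort, however often the test is re-applied.
    """

    label: str
    values: np.ndarray
    annotation: str = ""
    n_excluded: int = 0

    def __init__(self, label: str, values, annotation: str = "", n_excluded: int = 0) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.isfinite(arr).all():
            raise ValueError("values must be finite")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "annotation", annotation)
        object.__setattr__(self, "n_excluded", n_excluded)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: float
    pvalue: float
    degenerate: bool = False
    detail: dict = field(default_factory=dict)


def _require_n(s: GroupSeries, n: int) -> None:
    if s.n < n:
        raise ValueError(f"group {s.label!r} needs n >= {n}, got {s.n}")


def unpaired_t(a: GroupSeries, b: GroupSeries, welch: bool = False) -> TestResult:
    """Two-sided two-sample t test (equal-variance Student by default)."""
    _require_n(a, 2)
    _require_n(b, 2)
    degenerate = a.values.std(ddof=1) == 0 and b.values.std(ddof=1) == 0
    if degenerate and np.mean(a.values) == np.mean(b.values):
        # identical constants: no evidence of difference, flagged
        return TestResult("unpaired_t", 0.0, a.n + b.n - 2, 1.0, degenerate=True)
    res = sps.ttest_ind(a.values, b.values, equal_var=not welch)
    df = float(res.df)
    return TestResult(
        "unpaired_t" + ("_welch" if welch else ""),
        float(res.statistic),
        df,
        float(res.pvalue),
        degenerate=degenerate,
    )


def paired_t(x, y) -> TestResult:
    """Two-sided paired t test on per-animal differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if len(x) < 2:
        raise ValueError("need >= 2 complete pairs")
    d = x - y
    if np.all(d == d[0]):
        # zero spread of differences: t undefined (or infinite); flagged
        return TestResult("paired_t", np.nan, len(x) - 1, np.nan, degenerate=True)
    res = sps.ttest_rel(x, y)
    return TestResult("paired_t", float(res.statistic), float(len(x) - 1), float(res.pvalue))


def one_way_anova_tukey(groups: list[GroupSeries]) -> TestResult:
    """Ordinary one-way ANOVA plus Tukey HSD adjusted pairwise p values.

    The Tukey adjustment uses the studentized-range distribution (scipy's
    ``tukey_hsd``).  Pairwise rows are keyed by group label so the result
    is invariant to group order.
    """
    if len(groups) < 3:
        raise ValueError("one-way ANOVA with Tukey post hoc expects >= 3 groups")
    for g in groups:
        _require_n(g, 2)
    arrays = [g.values for g in groups]
    degenerate = np.ptp(np.concatenate(arrays)) == 0
    if degenerate:  # every observation identical: no variance anywhere
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*arrays)
    k = len(groups)
    n_tot = sum(g.n for g in groups)
    rows = []
    tk = None if degenerate else sps.tukey_hsd(*arrays)
    ci = None if tk is None else tk.confidence_interval()
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "group_a": groups[i].label,
                    "group_b": groups[j].label,
                    "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    "p_adj": 1.0 if tk is None else float(tk.pvalue[i, j]),
                    "ci_low": 0.0 if ci is None else float(ci.low[i, j]),
                    "ci_high": 0.0 if ci is None else float(ci.high[i, j]),
                }
            )
    table = pd.DataFrame(rows).sort_values(["group_a", "group_b"]).reset_index(drop=True)
    return TestResult(
        "one_way_anova_tukey",
        float(f),
        float(k - 1),
        float(p),
        degenerate=degenerate,
        detail={"df_within": n_tot - k, "tukey": table},
    )


def grubbs_critical_value(n: int, alpha: float = ALPHA) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t2 = sps.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_exclude(series: GroupSeries, alpha: float = ALPHA) -> tuple[GroupSeries, dict]:
    """Remove at most one outlying animal by the two-sided Grubbs test.

    Returns the (possibly reduced) series and a log with the statistic,
    critical value and the excluded value if any.  Never applied twice: one
    exclusion per cohort at most.  With n < 3, no test is run.
    """
    x = series.values
    log: dict = {"n": series.n, "alpha": alpha, "excluded": None}
    if series.n_excluded >= 1:
        log["warning"] = "one animal already excluded from this cohort"
        return series, log
    if series.n < 3:
        log["warning"] = "n < 3: Grubbs test not applicable"
        return series, log
    mean, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        log["warning"] = "zero variance: no outlier test"
        return series, log
    g = np.abs(x - mean) / sd
    i = int(np.argmax(g))
    crit = grubbs_critical_value(series.n, alpha)
    log.update({"G": float(g[i]), "critical": float(crit)})
    if g[i] > crit:
        log["excluded"] = float(x[i])
        kept = np.delete(x, i)
        return GroupSeries(series.label, kept, series.annotation, n_excluded=1), log
    return series, log


@dataclass(frozen=True)
class PoolingDecision:
    pooled: bool
    series: list[GroupSeries]
    pvalue: float

    @property
    def primary(self) -> GroupSeries:
        return self.series[0]


def pool_sham(
    sham_vehicle: GroupSeries, sham_isrib: GroupSeries, alpha: float = ALPHA
) -> PoolingDecision:
    """Pool the two sham arms when they do not differ (p >= alpha).

    Returns the pooled "Sham ± ISRIB" series when pooling applies,
    otherwise both arms unchanged with ``pooled=False``; downstream group
    comparisons should use ``primary`` when pooling occurred.
    """
    if sham_vehicle.n == 0 or sham_isrib.n == 0:
        raise ValueError("both sham arms must be non-empty")
    res = unpaired_t(sham_vehicle, sham_isrib)
    if res.pvalue >= alpha:
        pooled = GroupSeries(
            "Sham ± ISRIB",
            np.concatenate([sham_vehicle.values, sham_isrib.values]),
            annotation=sham_vehicle.annotation,
        )
        return PoolingDecision(True, [pooled], res.pvalue)
    return PoolingDecision(False, [sham_vehicle, sham_isrib], res.pvalue)
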