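"""Group inferential statistics: t-tests, mixed ANOVA, correlations, FDR.

Conventions: pooled-variance (Student) two-sample t by default with
df = n1 + n2 - 2 (Welch available by flag, used only for the one global-FC
contrast reported with fractional df); Cohen's d from the pooled SD, with
the sign retained in machine output and the magnitude shown in report
tables; two-sided p values throughout; Benjamini-Hochberg step-up FDR at
q < 0.10 with one family per report table.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TwoGroupSummary",
    "TTestResult",
    "AnovaResult",
    "CorrelationCell",
    "DegenerateVarianceError",
    "two_sample_t",
    "two_sample_t_from_data",
    "paired_t",
    "mixed_anova_2x2",
    "correlation_table",
    "bh_fdr",
    "apply_fdr",
]


class DegenerateVarianceError(ValueError):
    """A t statistic overflowed (zero variance with nonzero mean difference)."""


@dataclass(frozen=True)
class TwoGroupSummary:
    """Sufficient statistics of a two-group comparison."""

    n1: int
    n2: int
    m1: float
    m2: float
    s1: float
    s2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("SDs must be non-negative")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    d: float | None = None
    welch: bool = False


def _pooled_sd(s: TwoGroupSummary) -> float:
    df = s.n1 + s.n2 - 2
    return float(np.sqrt(((s.n1 - 1) * s.s1**2 + (s.n2 - 1) * s.s2**2) / df))


def two_sample_t(summary: TwoGroupSummary, welch: bool = False) -> TTestResult:
    """Independent-samples t with Cohen's d from the printed-style summary.

    Student (pooled) by default: t = (m1-m2)/(s_p*sqrt(1/n1+1/n2)),
    df = n1+n2-2, d = (m1-m2)/s_p.
    """
    s = summary
    sp = _pooled_sd(s)
    if sp == 0:
        if s.m1 != s.m2:
            raise DegenerateVarianceError(
                "zero pooled variance with unequal means: t is infinite"
            )
        return TTestResult(0.0, s.n1 + s.n2 - 2, 1.0, 0.0, welch)
    res = sps.ttest_ind_from_stats(
        s.m1, s.s1, s.n1, s.m2, s.s2, s.n2, equal_var=not welch
    )
    if welch:
        v1, v2 = s.s1**2 / s.n1, s.s2**2 / s.n2
        df = (v1 + v2) ** 2 / (v1**2 / (s.n1 - 1) + v2**2 / (s.n2 - 1))
    else:
        df = float(s.n1 + s.n2 - 2)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue), (s.m1 - s.m2) / sp, welch)


def two_sample_t_from_data(x, y, welch: bool = False) -> TTestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_t(
        TwoGroupSummary(len(x), len(y), x.mean(), y.mean(), x.std(ddof=1), y.std(ddof=1)),
        welch=welch,
    )


def paired_t(x, y) -> TTestResult:
    """Paired t as a one-sample t on the differences, df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired series must be 1-D and equal length")
    if len(x) < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        if d.mean() != 0:
            raise DegenerateVarianceError(
                "constant nonzero difference: paired t is infinite"
            )
        return TTestResult(0.0, len(d) - 1, 1.0)
    res = sps.ttest_rel(x, y)
    return TTestResult(float(res.statistic), float(len(d) - 1), float(res.pvalue))


@dataclass(frozen=True)
class AnovaResult:
    """2x2 mixed ANOVA effects, each as (F, df1, df2, p, partial eta^2)."""

    task: tuple
    diagnosis: tuple
    interaction: tuple

    def as_dict(self) -> dict:
        keys = ("F", "df1", "df2", "p", "partial_eta_sq")
        return {
            name: dict(zip(keys, vals))
            for name, vals in (
                ("task", self.task),
                ("diagnosis", self.diagnosis),
                ("interaction", self.interaction),
            )
        }


def mixed_anova_2x2(
    table: pd.DataFrame,
    dv: str = "rt",
    within: str = "task",
    between: str = "group",
    subject: str = "subject",
) -> AnovaResult:
    """Mixed-design 2(diagnosis, between) x 2(task, within) ANOVA.

    Expects one row per subject x within-level, complete cases, exactly
    two groups and two within levels. Partial eta^2 per effect is
    SS_effect / (SS_effect + SS_error-of-that-stratum).
    """
    import pingouin as pg

    t = table[[subject, between, within, dv]].dropna()
    if t[between].nunique() != 2 or t[within].nunique() != 2:
        raise ValueError("design must have exactly 2 groups and 2 within levels")
    counts = t.groupby([subject, within]).size()
    if (counts != 1).any():
        raise ValueError("duplicated subject x level rows")
    per_subject = t.groupby(subject)[within].nunique()
    if (per_subject != 2).any():
        missing = per_subject[per_subject != 2].index.tolist()
        raise ValueError(f"missing within-level cell for subjects: {missing[:5]}")
    aov = pg.mixed_anova(
        data=t, dv=dv, within=within, between=between, subject=subject
    ).set_index("Source")
    within_row = aov.loc[within]
    between_row = aov.loc[between]
    inter_row = aov.loc["Interaction"]

    def row(r):
        return (float(r["F"]), float(r["DF1"]), float(r["DF2"]), float(r["p_unc"]), float(r["np2"]))

    return AnovaResult(task=row(within_row), diagnosis=row(between_row), interaction=row(inter_row))


@dataclass(frozen=True)
class CorrelationCell:
    variable_x: str
    variable_y: str
    r: float
    p: float
    n: int
    group: str | None = None
    fdr_significant: bool | None = None


def correlation_table(
    measures: pd.DataFrame,
    pairs: list[tuple[str, str]],
    group_col: str | None = None,
) -> list[CorrelationCell]:
    """Pairwise-complete Pearson r with two-sided p for requested pairs.

    With ``group_col`` the correlations are computed within each level of
    that column (the convention for FC-behaviour cells); without it they
    are computed over all rows (behaviour-behaviour cells).
    """
    def one(frame: pd.DataFrame, x: str, y: str, group):
        sub = frame[[x, y]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"fewer than 3 complete cases for ({x}, {y})")
        r, p = sps.pearsonr(sub[x], sub[y])
        return CorrelationCell(x, y, float(r), float(p), n, group)

    cells = []
    for x, y in pairs:
        if group_col is None:
            cells.append(one(measures, x, y, None))
        else:
            for g, frame in measures.groupby(group_col, sort=True):
                cells.append(one(frame, x, y, str(g)))
    return cells


def bh_fdr(p_values, q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR level q.

    Sort p ascending, find the largest k with p_(k) <= k*q/m, reject the k
    smallest; flags are returned in the original order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def apply_fdr(cells: list[CorrelationCell], q: float = 0.10) -> list[CorrelationCell]:
    """Flag a family of correlation cells by BH-FDR at level q."""
    from dataclasses import replace

    flags = bh_fdr([c.p for c in cells], q)
    return [replace(c, fdr_significant=bool(f)) for c, f in zip(cells, flags)]
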