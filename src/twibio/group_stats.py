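"""Two-sample group inference on ROI and biomarker measures.

Implements the independent two-sample t-test (Student pooled-variance by
default, Welch–Satterthwaite as an option), the t→p conversion used to
report two-sided significance, and mean ± SEM summaries, plus a long-format
batch comparison over a measurement table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "t_test",
    "t_to_p",
    "summarize",
    "round_p",
    "compare_table",
]


@dataclass(frozen=True)
class GroupComparison:
    """Result of an independent two-sample t-test.

    ``sem`` is the sample standard deviation (n−1 denominator) divided by
    the square root of the group size, matching mean ± s.e.m. reporting.
    """

    t: float
    df: float
    p: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int
    variant: str = "student"


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean.

    SEM uses the n−1 (sample) standard deviation; a single observation has
    SEM 0 by convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in sample")
    mean = float(v.mean())
    if v.size == 1:
        return mean, 0.0
    sem = float(v.std(ddof=1) / math.sqrt(v.size))
    return mean, sem


def t_to_p(t: float, df: float) -> float:
    """Two-sided p-value for a t statistic: p = 2·(1 − F_t(|t|; df)).

    The survival function of the t distribution is evaluated through the
    regularized incomplete beta function (scipy's implementation).
    """
    if df <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    return float(2.0 * stats.t.sf(abs(t), df))


def round_p(p: float, decimals: int = 3) -> float:
    """Round a p-value half-away-from-zero (the convention of printed
    tables, unlike numpy's banker's rounding)."""
    scale = 10**decimals
    return math.floor(p * scale + 0.5) / scale


def t_test(a, b, variant: str = "student") -> GroupComparison:
    """Independent two-sample t-test.

    variant="student": pooled variance, df = n_a + n_b − 2.
    variant="welch":   unpooled variance, Satterthwaite df.

    Two groups with zero variance and equal means give t = 0, p = 1
    rather than a 0/0 failure.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant: {variant!r}")

    mean_a, sem_a = summarize(a)
    mean_b, sem_b = summarize(b)

    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if mean_a == mean_b:
            t_stat, df, p = 0.0, float(a.size + b.size - 2), 1.0
        else:
            t_stat = math.inf if mean_a > mean_b else -math.inf
            df, p = float(a.size + b.size - 2), 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
        t_stat = float(res.statistic)
        df = float(res.df)
        p = float(res.pvalue)

    return GroupComparison(
        t=t_stat, df=df, p=p,
        mean_a=mean_a, sem_a=sem_a, mean_b=mean_b, sem_b=sem_b,
        n_a=int(a.size), n_b=int(b.size), variant=variant,
    )


def compare_table(
    data: pd.DataFrame,
    group_col: str = "group",
    measure_col: str = "measure",
    value_col: str = "value",
    variant: str = "student",
    fdr: bool = False,
) -> pd.DataFrame:
    """Run a two-sample t-test for every measure in a long-format table.

    The two group labels are taken in sorted order (group A first). With
    ``fdr=True`` a Benjamini–Hochberg adjusted q-value column is appended;
    by default no multiplicity correction is applied.
    """
    groups = sorted(data[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    ga, gb = groups
    rows = []
    for measure, sub in data.groupby(measure_col, sort=True):
        a = sub.loc[sub[group_col] == ga, value_col].dropna().to_numpy()
        b = sub.loc[sub[group_col] == gb, value_col].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        cmp = t_test(a, b, variant=variant)
        rows.append(
            {
                "measure": measure,
                "group_a": ga,
                "group_b": gb,
                "n_a": cmp.n_a,
                "n_b": cmp.n_b,
                "mean_a": cmp.mean_a,
                "sem_a": cmp.sem_a,
                "mean_b": cmp.mean_b,
                "sem_b": cmp.sem_b,
                "t": cmp.t,
                "df": cmp.df,
                "p": cmp.p,
            }
        )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
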