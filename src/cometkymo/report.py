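"""Group summaries, fold-change tables and significance testing.

The significance test is the classic two-sample equal-variance (pooled-SD)
Student t-test with a two-tailed p from the t distribution on n1 + n2 - 2
degrees of freedom, matching how per-embryo measurements are compared
between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class SummaryRow:
    group: str
    n: int
    mean: float
    sd: float
    sem: float
    fold_vs_control: float


def two_sample_t(a, b) -> TTestResult:
    """Equal-variance two-sample t-test, two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        # zero pooled variance with equal means: no evidence either way
        return TTestResult(t=0.0, df=a.size + b.size - 2, p=1.0)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), df=a.size + b.size - 2, p=float(res.pvalue))


def summarize_groups(table: pd.DataFrame, control: str, group_col: str = "group",
                     value_col: str = "value") -> list[SummaryRow]:
    """Per-group n/mean/SD/SEM and fold versus the control group mean.

    Groups are ordered control first, then alphabetically.
    """
    if control not in set(table[group_col]):
        raise ValueError(f"control group {control!r} not present")
    ctrl_mean = float(table.loc[table[group_col] == control, value_col].mean())
    rows = []
    labels = sorted(table[group_col].unique(), key=lambda g: (g != control, g))
    for g in labels:
        vals = table.loc[table[group_col] == g, value_col].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(SummaryRow(
            group=str(g), n=int(vals.size), mean=float(vals.mean()), sd=sd,
            sem=sd / np.sqrt(vals.size) if vals.size else float("nan"),
            fold_vs_control=float(vals.mean() / ctrl_mean) if ctrl_mean != 0 else float("nan"),
        ))
    return rows


def summary_frame(rows: list[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def build_report(tables: list[pd.DataFrame], control: str, group_col: str = "group",
                 value_col: str = "value") -> tuple[pd.DataFrame, dict]:
    """Assemble summaries plus pairwise tests of every group against control.

    Pure function of its inputs; identical inputs give identical outputs.
    p-values are rounded to 3 significant figures; no multiple-testing
    correction is applied.
    """
    table = pd.concat(tables, ignore_index=True)
    rows = summarize_groups(table, control, group_col, value_col)
    frame = summary_frame(rows)
    ctrl_vals = table.loc[table[group_col] == control, value_col].to_numpy(dtype=float)
    tests = {}
    for r in rows:
        if r.group == control or r.n < 2 or ctrl_vals.size < 2:
            continue
        vals = table.loc[table[group_col] == r.group, value_col].to_numpy(dtype=float)
        try:
            res = two_sample_t(vals, ctrl_vals)
        except ValueError:
            continue
        tests[r.group] = {"t": res.t, "df": res.df, "p": float(f"{res.p:.3g}")}
    summary = {
        "control": control,
        "groups": {r.group: {"n": r.n, "mean": r.mean, "sd": r.sd, "sem": r.sem,
                             "fold_vs_control": r.fold_vs_control} for r in rows},
        "t_tests_vs_control": tests,
        "dispersion_convention": "SD of per-sample ratios to the control mean",
    }
    return frame, summary
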