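"""Replicate aggregation and variance F-tests for test-retest precision.

The core question is whether repositioning a phantom between replicate
acquisitions degrades the precision of a quantitative uptake metric. For
each (target, metric, reconstruction) cell the repositioned and stationary
replicate series are compared with a two-sample variance F-test:
``F = s2_a / s2_b`` against the F(n_a - 1, n_b - 1) distribution, two-sided
(p = 2 min(P(F' <= F), P(F' >= F)), capped at 1). P-values are reported
uncorrected for multiple comparisons; a Holm-corrected column can be added
on request. Normality of the replicate recovery coefficients is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FTestResult",
    "replicate_summary",
    "variance_f_test",
    "variance_inflation",
    "precision_table",
    "format_precision_table",
    "boxplot_summary",
]


@dataclass(frozen=True)
class FTestResult:
    f_statistic: float
    df: tuple  # (n_a - 1, n_b - 1)
    p_value: float
    variance_ratio: float  # s2_a / s2_b (a = repositioned by convention)
    significant: bool
    alpha: float
    degenerate: bool = False


def replicate_summary(values) -> dict:
    """Mean, sample SD (n-1), CV, median, min, max of one replicate series."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("replicate summary needs at least two values")
    if not np.all(np.isfinite(v)):
        raise ValueError("replicate values must be finite")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return {
        "n": len(v),
        "mean": mean,
        "sd": sd,
        "cv": sd / mean if mean != 0 else float("inf"),
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
    }


def variance_f_test(a, b, alpha: float = 0.05) -> FTestResult:
    """Two-sided variance-ratio test between two replicate series.

    Degenerate conventions: both variances zero -> F = 1, p = 1; exactly
    one variance zero -> p = 0 and the result is flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    df = (len(a) - 1, len(b) - 1)
    if va == 0.0 and vb == 0.0:
        return FTestResult(1.0, df, 1.0, 1.0, False, alpha, degenerate=True)
    if vb == 0.0:
        return FTestResult(float("inf"), df, 0.0, float("inf"), True, alpha, degenerate=True)
    f = va / vb
    if va == 0.0:
        return FTestResult(0.0, df, 0.0, 0.0, True, alpha, degenerate=True)
    dist = sps.f(*df)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    p = float(min(p, 1.0))
    return FTestResult(float(f), df, p, float(f), p < alpha, alpha)


def variance_inflation(repositioned, stationary) -> float:
    """Variance ratio s2_repositioned / s2_stationary (inf if stationary is exact)."""
    r = np.asarray(repositioned, dtype=float)
    s = np.asarray(stationary, dtype=float)
    vr = float(r.var(ddof=1))
    vs = float(s.var(ddof=1))
    if vs == 0.0:
        return float("inf") if vr > 0 else 1.0
    return vr / vs


def precision_table(
    records: pd.DataFrame,
    *,
    value_col: str = "rc",
    target_col: str = "target",
    metric_col: str = "metric",
    recon_col: str = "recon_label",
    condition_col: str = "condition",
    repositioned: str = "repositioned",
    stationary: str = "stationary",
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """F-test p-values per target row, one column per (recon, metric).

    Tidy output: one row per (target, recon, metric) with the F statistic,
    variance ratio, p-value and significance flag; cells missing one
    condition get NaN statistics and ``status='missing'`` instead of
    aborting the run. With ``holm=True`` a Holm-adjusted p-value column is
    appended (off by default, matching the uncorrected presentation).
    """
    required = {value_col, target_col, metric_col, recon_col, condition_col}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing columns: {sorted(missing_cols)}")
    rows = []
    grouped = records.groupby([target_col, recon_col, metric_col], sort=True, dropna=False)
    for (target, recon, metric), g in grouped:
        a = g.loc[g[condition_col] == repositioned, value_col].dropna().to_numpy()
        b = g.loc[g[condition_col] == stationary, value_col].dropna().to_numpy()
        row = {"target": target, "recon": recon, "metric": metric}
        if len(a) < 2 or len(b) < 2:
            row.update(
                f=np.nan, p=np.nan, variance_ratio=np.nan, significant=False, status="missing"
            )
        else:
            res = variance_f_test(a, b, alpha)
            row.update(
                f=res.f_statistic,
                p=res.p_value,
                variance_ratio=res.variance_ratio,
                significant=res.significant,
                status="degenerate" if res.degenerate else "ok",
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if holm and len(out):
        ok = out["status"] == "ok"
        p = out.loc[ok, "p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
        out.loc[ok, "p_holm"] = adj
    return out


def format_precision_table(table: pd.DataFrame, alpha: float = 0.05) -> str:
    """Markdown rendering: rows = targets, columns = recon x metric,
    non-significant cells shown as an en dash."""
    if not len(table):
        return "(no cells)"

    def cell(row):
        if row["status"] == "missing":
            return "missing"
        if not row["significant"]:
            return "–"
        p = row["p"]
        return f"{p:.3f}" if p >= 0.001 else f"{p:.1e}"

    tab = table.copy()
    tab["cell"] = tab.apply(cell, axis=1)
    wide = tab.pivot_table(
        index="target",
        columns=["recon", "metric"],
        values="cell",
        aggfunc="first",
        sort=True,
    )
    wide.columns = [f"{r} ({m})" for r, m in wide.columns]
    lines = ["| target | " + " | ".join(wide.columns) + " |"]
    lines.append("|" + "---|" * (len(wide.columns) + 1))
    for target, row in wide.iterrows():
        lines.append(f"| {target} | " + " | ".join(str(x) for x in row) + " |")
    return "\n".join(lines)


def boxplot_summary(records: pd.DataFrame, group_cols, value_col: str = "rc") -> list:
    """Median / SD-box / range summaries per group (the plotting convention:
    box = +-1 SD around the mean, whiskers = range, line = median)."""
    out = []
    for key, g in records.groupby(list(group_cols), sort=True):
        v = g[value_col].dropna().to_numpy()
        if len(v) < 2:
            continue
        s = replicate_summary(v)
        entry = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        entry.update(
            median=s["median"],
            box_low=s["mean"] - s["sd"],
            box_high=s["mean"] + s["sd"],
            whisker_low=s["min"],
            whisker_high=s["max"],
            n=s["n"],
        )
        out.append(entry)
    return out
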