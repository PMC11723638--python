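"""Simplified statistical summaries and the cross-model comparison report.

The published analyses use heterogeneous-variance linear mixed-effects
models with planned contrasts; those are not fully specified by the text,
so this module substitutes per-subject ordinary least squares regressions
aggregated by one-sample t-tests.  The substitution is stated in the
rendered report header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ZeroVarianceError

__all__ = ["RegressionSummary", "regress", "one_sample_t",
           "model_comparison_report", "render_report"]

_REPORT_NOTE = (
    "Statistics are simplified relative to the original mixed-effects "
    "analysis: per-subject OLS regressions are aggregated with one-sample "
    "t-tests of the slopes against zero."
)


@dataclass(frozen=True)
class RegressionSummary:
    """OLS slope with its 95% CI and p-value (t distribution, n-2 df)."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    def __post_init__(self):
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("CI must contain the slope")


def regress(x, y) -> RegressionSummary:
    """Ordinary least squares of y on x with 95% CI and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    df = x.size - 2
    tcrit = stats.t.ppf(0.975, df)
    half = tcrit * res.stderr
    return RegressionSummary(slope=float(res.slope),
                             intercept=float(res.intercept),
                             ci_low=float(res.slope - half),
                             ci_high=float(res.slope + half),
                             p_value=float(res.pvalue), n=int(x.size))


def one_sample_t(values, mu0: float):
    """One-sample t-test; returns (t, df, p)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(v) == 0:
        raise ZeroVarianceError("values have zero variance; t undefined")
    res = stats.ttest_1samp(v, mu0)
    return float(res.statistic), int(v.size - 1), float(res.pvalue)


def _subject_slopes(df: pd.DataFrame, xcol: str, ycol: str) -> pd.Series:
    slopes = {}
    for subject, grp in df.groupby("subject"):
        grp = grp.dropna(subset=[xcol, ycol])
        if len(grp) >= 3 and np.ptp(grp[xcol].to_numpy()) > 0:
            slopes[subject] = regress(grp[xcol], grp[ycol]).slope
    return pd.Series(slopes, dtype=float)


def model_comparison_report(fits: pd.DataFrame,
                            metrics: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Aggregate fit and metric tables into per-model summaries.

    ``fits`` needs columns subject, block, trial_index, model, vaf, K, B
    (rows with status != "ok" are ignored if a status column is present);
    ``metrics`` needs subject, block, trial_index, duration, peak_ratio,
    interpeak_min.  Pure function of its inputs.

    Returns ``{"summary": ..., "criteria": ...}``: per model x block means
    and SDs, and a boolean criteria matrix (peak ratio > 1, negative
    inter-peak-velocity-vs-duration slope, highest mean VAF).
    """
    fits = fits.copy()
    if "status" in fits.columns:
        fits = fits[fits["status"] == "ok"]
    rows = []
    crit_rows = []
    for model, fgrp in fits.groupby("model"):
        merged = fgrp.merge(
            metrics, on=["subject", "block", "trial_index"],
            suffixes=("_fit", ""))
        for block, bgrp in merged.groupby("block"):
            slopes = _subject_slopes(bgrp, "duration", "interpeak_min")
            slope_mean = float(slopes.mean()) if len(slopes) else math.nan
            if len(slopes) >= 2 and np.ptp(slopes.to_numpy()) > 0:
                _, _, slope_p = one_sample_t(slopes, 0.0)
            else:
                slope_p = math.nan
            rows.append({
                "model": model, "block": block, "n_trials": len(bgrp),
                "peak_ratio_mean": bgrp["peak_ratio"].mean(),
                "peak_ratio_sd": bgrp["peak_ratio"].std(),
                "interpeak_slope_mean": slope_mean,
                "interpeak_slope_p": slope_p,
                "vaf_mean": bgrp["vaf"].mean(),
                "vaf_sd": bgrp["vaf"].std(),
                "K_mean": bgrp["K"].mean(), "K_sd": bgrp["K"].std(),
                "B_mean": bgrp["B"].mean(), "B_sd": bgrp["B"].std(),
            })
    summary = pd.DataFrame(rows)
    if len(summary):
        for block, sgrp in summary.groupby("block"):
            best = sgrp.loc[sgrp["vaf_mean"].idxmax(), "model"]
            for _, row in sgrp.iterrows():
                crit_rows.append({
                    "model": row["model"], "block": block,
                    "peak_ratio_gt_1": bool(row["peak_ratio_mean"] > 1),
                    "negative_interpeak_slope": bool(
                        row["interpeak_slope_mean"] < 0),
                    "highest_vaf": row["model"] == best,
                })
    criteria = pd.DataFrame(crit_rows)
    return {"summary": summary, "criteria": criteria}


def render_report(tables: dict[str, pd.DataFrame]) -> str:
    """Markdown rendering of the comparison report."""
    lines = ["# Model comparison report", "", f"> {_REPORT_NOTE}", ""]
    for name, df in tables.items():
        lines.append(f"## {name}")
        lines.append("")
        lines.append("```")
        lines.append(df.to_string(index=False))
        lines.append("```")
        lines.append("")
    return "\n".join(lines)
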