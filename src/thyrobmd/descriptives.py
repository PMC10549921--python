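"""Descriptive statistics, exceedance fractions and Spearman correlation.

Quantiles use linear interpolation between order statistics (the "type 7"
convention).  Spearman correlation is computed on average ranks; two-sided
p-values come from the t approximation t = r*sqrt((n-2)/(1-r^2)) on n-2
degrees of freedom, and 95% confidence intervals from the Fisher
z-transform with the Fieller-corrected standard error sqrt(1.06/(n-3)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "quantiles",
    "fraction_above",
    "spearman_with_ci",
    "summary_table",
    "correlation_table",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with 95% CI and two-sided p-value."""

    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def quantiles(values) -> tuple[float, float, float]:
    """(p25, median, p75) of the non-missing values, linear interpolation."""
    arr = _clean(values)
    if arr.size == 0:
        raise ValueError("quantiles requires at least one non-missing value")
    p25, med, p75 = np.percentile(arr, [25, 50, 75])
    return float(p25), float(med), float(p75)


def fraction_above(values, threshold: float) -> float:
    """Percent of non-missing values strictly greater than ``threshold``."""
    if not np.isfinite(threshold):
        if np.isnan(threshold):
            raise ValueError("threshold must not be NaN")
        # ±inf thresholds are well-defined limits (100% / 0%)
    arr = _clean(values)
    if arr.size == 0:
        raise ValueError("fraction_above requires at least one non-missing value")
    return float(100.0 * np.mean(arr > threshold))


def spearman_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Spearman correlation of pairwise-complete (x, y) with CI and p-value.

    Pairs with either value missing are removed; at least 3 complete pairs
    are required.  Ties receive average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined: zero variance in ranks")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])

    # two-sided p via the t approximation
    r_clipped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clipped * np.sqrt((n - 2) / (1.0 - r_clipped**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))

    # Fisher z CI with Fieller-corrected SE
    if n <= 3:
        ci_low, ci_high = -1.0, 1.0
    else:
        z = np.arctanh(r_clipped)
        se = np.sqrt(1.06 / (n - 3))
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        ci_low = float(np.tanh(z - zcrit * se))
        ci_high = float(np.tanh(z + zcrit * se))
    return CorrelationResult(r=r, ci_low=ci_low, ci_high=ci_high, p=p, n=int(n))


def _iter_strata(
    frame: pd.DataFrame, stratum_col: str, include_entire: bool
) -> Iterable[tuple[str, pd.DataFrame]]:
    if stratum_col in frame.columns:
        for label in sorted(frame[stratum_col].dropna().unique()):
            yield str(label), frame[frame[stratum_col] == label]
    if include_entire:
        yield "entire", frame


def summary_table(
    frame: pd.DataFrame,
    variables: Sequence[str],
    stratum_col: str = "sex",
    include_entire: bool = True,
) -> pd.DataFrame:
    """Per-stratum p25/median/p75/n for each variable (Table-4 style layout)."""
    rows = []
    for label, sub in _iter_strata(frame, stratum_col, include_entire):
        for var in variables:
            values = _clean(sub[var]) if var in sub.columns else np.array([])
            if values.size == 0:
                rows.append(
                    {"stratum": label, "variable": var, "p25": np.nan,
                     "median": np.nan, "p75": np.nan, "n": 0}
                )
                continue
            p25, med, p75 = quantiles(values)
            rows.append(
                {"stratum": label, "variable": var, "p25": p25,
                 "median": med, "p75": p75, "n": int(values.size)}
            )
    return pd.DataFrame(rows)


def correlation_table(
    frame: pd.DataFrame,
    x_col: str,
    y_cols: Sequence[str],
    stratum_col: str = "sex",
    include_entire: bool = True,
    min_n: int = 3,
) -> pd.DataFrame:
    """Spearman correlations of ``x_col`` against each ``y_col`` per stratum.

    Mirrors the layout of per-pair correlation report tables: one row per
    (stratum, pair), columns r / ci_low / ci_high / p / n.  Pairs with fewer
    than ``min_n`` complete observations get NaN statistics.
    """
    rows = []
    for label, sub in _iter_strata(frame, stratum_col, include_entire):
        for y_col in y_cols:
            base = {"stratum": label, "x": x_col, "y": y_col}
            try:
                res = spearman_with_ci(sub[x_col], sub[y_col])
            except ValueError:
                rows.append({**base, "r": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p": np.nan, "n": 0})
                continue
            rows.append({**base, "r": res.r, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)
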