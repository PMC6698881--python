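"""Quantile analysis of within-pair polygenic-score differences.

Co-twin score differences are split into deciles of their absolute
magnitude; the outcome contrast between the lowest and highest decile, and a
regression through the origin of outcome differences on score differences,
quantify how much phenotypic difference an observed within-pair genetic
difference predicts. Because both difference variables negate under a swap
of twin labels, the through-origin fit has no intercept and the decile
contrast is computed on outcome differences oriented toward the
higher-scoring twin (so a positive contrast means the twin with the higher
score has the higher outcome).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .decomposition import validate_pairs

__all__ = [
    "pair_differences", "decile_split", "extreme_decile_test",
    "origin_regression", "decile_table", "back_transform",
    "ExtremeDecileResult", "OriginRegressionResult",
]


def pair_differences(cohort: pd.DataFrame, gps_col: str,
                     outcome_col: str) -> pd.DataFrame:
    """One row per family: member-1 minus member-2 differences.

    Twin order follows the ``member`` labels (elder twin first where known).
    Incomplete pairs are dropped.
    """
    df, _ = validate_pairs(cohort, [gps_col, outcome_col])
    g1, g2 = df[gps_col].to_numpy()[0::2], df[gps_col].to_numpy()[1::2]
    y1, y2 = df[outcome_col].to_numpy()[0::2], df[outcome_col].to_numpy()[1::2]
    out = pd.DataFrame({
        "family_id": df["family_id"].to_numpy()[0::2],
        "gps_diff": g1 - g2,
        "outcome_diff": y1 - y2,
    })
    out["abs_gps_diff"] = out["gps_diff"].abs()
    return out


def decile_split(table: pd.DataFrame, n_quantiles: int = 10) -> pd.DataFrame:
    """Assign rank-based deciles of ``abs_gps_diff`` (1 = smallest).

    Group sizes differ by at most one; ties break by stable input order so
    the assignment is deterministic.
    """
    n = len(table)
    if n < n_quantiles:
        raise ValueError(f"need at least {n_quantiles} pairs, got {n}")
    order = np.argsort(table["abs_gps_diff"].to_numpy(), kind="stable")
    dec = np.empty(n, dtype=int)
    for q, chunk in enumerate(np.array_split(order, n_quantiles), start=1):
        dec[chunk] = q
    out = table.copy()
    out["decile"] = dec
    return out


@dataclass
class ExtremeDecileResult:
    mean_low: float
    mean_high: float
    contrast: float
    t: float
    p: float
    n_low: int
    n_high: int
    oriented: bool


def extreme_decile_test(table: pd.DataFrame,
                        oriented: bool = True) -> ExtremeDecileResult:
    """Welch test of mean outcome differences: lowest vs highest decile.

    ``oriented=True`` signs each outcome difference toward the
    higher-scoring twin (sign of gps_diff applied to outcome_diff), making
    the contrast directionally interpretable; ``oriented=False`` uses
    absolute outcome differences.
    """
    if "decile" not in table.columns:
        raise ValueError("run decile_split first")
    hi_q = int(table["decile"].max())
    if oriented:
        vals = np.sign(table["gps_diff"].to_numpy()) * \
            table["outcome_diff"].to_numpy()
    else:
        vals = table["outcome_diff"].abs().to_numpy()
    low = vals[table["decile"].to_numpy() == 1]
    high = vals[table["decile"].to_numpy() == hi_q]
    if low.size == 0 or high.size == 0:
        raise ValueError("empty extreme decile")
    t, p = stats.ttest_ind(high, low, equal_var=False)
    return ExtremeDecileResult(
        mean_low=float(low.mean()), mean_high=float(high.mean()),
        contrast=float(high.mean() - low.mean()), t=float(t), p=float(p),
        n_low=int(low.size), n_high=int(high.size), oriented=oriented)


@dataclass
class OriginRegressionResult:
    slope: float
    se: float
    t: float
    p: float
    r2: float
    n: int


def origin_regression(table: pd.DataFrame) -> OriginRegressionResult:
    """No-intercept OLS of outcome differences on score differences.

    R^2 is the uncentered coefficient of determination
    1 - SS_res / sum(outcome_diff^2), the standard definition for
    through-origin fits.
    """
    x = table["gps_diff"].to_numpy(dtype=float)
    y = table["outcome_diff"].to_numpy(dtype=float)
    if np.all(x == 0):
        raise ValueError("all score differences are zero; slope undefined")
    res = sm.OLS(y, x[:, None]).fit()
    return OriginRegressionResult(
        slope=float(res.params[0]), se=float(res.bse[0]),
        t=float(res.tvalues[0]), p=float(res.pvalues[0]),
        r2=float(res.rsquared), n=int(x.size))


def decile_table(table: pd.DataFrame, oriented: bool = True) -> pd.DataFrame:
    """Per-decile summary: n, mean |score diff|, mean outcome diff, 95% CI."""
    if "decile" not in table.columns:
        raise ValueError("run decile_split first")
    if oriented:
        vals = np.sign(table["gps_diff"]) * table["outcome_diff"]
    else:
        vals = table["outcome_diff"].abs()
    t = table.assign(_val=vals)
    rows = []
    for dec, grp in t.groupby("decile"):
        m = grp["_val"].mean()
        se = grp["_val"].std(ddof=1) / np.sqrt(len(grp)) if len(grp) > 1 else np.nan
        half = 1.959963984540054 * se
        rows.append({"decile": dec, "n": len(grp),
                     "mean_abs_gps_diff": grp["abs_gps_diff"].mean(),
                     "mean_outcome_diff": m,
                     "ci_low": m - half, "ci_high": m + half})
    return pd.DataFrame(rows)


def back_transform(values_z, mean: float, sd: float) -> np.ndarray:
    """Map z-scaled values back to a raw scale (e.g. IQ: mean 100, SD 15).

    For difference scores pass ``mean=0`` — a difference of z-scores
    rescales by the SD alone.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    return np.asarray(values_z, dtype=float) * sd + mean
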