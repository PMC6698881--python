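"""Pair-resampling bootstrap inference for the within/between decomposition.

The resampling unit is always the family: whole DZ twin pairs are drawn with
replacement to the original pair count, the decomposition model is refit per
replicate, and 95% percentile intervals come from the empirical 2.5/97.5
replicate quantiles. The same resampled families feed every requested
covariate set, so contrasts between models (e.g. the between-family
coefficient before vs after SES adjustment) are computed on paired
replicates — differencing unpaired replicate streams would inflate the
spread of the difference distribution.

Difference tests divide the point-estimate difference by the standard
deviation of the replicate difference distribution, referred to a standard
normal. Attenuation is the percentage change 100 (bB - bW)/bB. Multiple
testing uses the Benjamini-Hochberg step-up rule: the corrected threshold is
the largest p(k) with p(k) <= (k/m) alpha.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import (DecompositionFit, WithinBetweenRegression,
                            fit_within_between, validate_pairs, _reml_pairs)

__all__ = [
    "BootstrapResult", "bootstrap_pairs", "diff_test", "attenuation",
    "covariate_shift_test", "bh_fdr", "DiffTestResult", "AttenuationResult",
    "ShiftTestResult", "BHResult",
]


@dataclass
class BootstrapResult:
    """Replicate draws of (beta_w, beta_b) for one or more covariate sets.

    ``fits`` holds the full-sample point fits per model name; ``replicates``
    maps each name to an (n_boot, 2) array with columns (beta_w, beta_b).
    Models sharing a BootstrapResult were refit on identical resamples.
    """

    n_boot: int
    seed: int | None
    n_pairs: int
    fits: dict
    replicates: dict
    n_failed: dict

    def ci(self, model: str = "base", coef: str = "beta_w",
           level: float = 0.95) -> tuple[float, float]:
        """Percentile interval for ``coef`` ('beta_w' or 'beta_b')."""
        col = {"beta_w": 0, "beta_b": 1}[coef]
        reps = self.replicates[model][:, col]
        lo = 100 * (1 - level) / 2
        return (float(np.nanpercentile(reps, lo)),
                float(np.nanpercentile(reps, 100 - lo)))

    def summary_row(self, model: str = "base") -> dict:
        fit = self.fits[model]
        wlo, whi = self.ci(model, "beta_w")
        blo, bhi = self.ci(model, "beta_b")
        return {"model": model, "beta_w": fit.beta_w, "beta_w_ci_low": wlo,
                "beta_w_ci_high": whi, "beta_b": fit.beta_b,
                "beta_b_ci_low": blo, "beta_b_ci_high": bhi}


def _pair_arrays(df: pd.DataFrame, outcome: str, predictor: str,
                 covariates: Sequence[str]):
    y = df[outcome].to_numpy(dtype=float)
    X = df[[predictor, *covariates]].to_numpy(dtype=float)
    return y, X


def _betas_no_covariates(y1, y2, x1, x2):
    """Closed-form fixed effects for the covariate-free pair model.

    The REML fixed effects decouple: beta_w is the through-origin slope of
    co-twin differences, beta_b the intercept-included slope of pair means.
    """
    dx, dy = x1 - x2, y1 - y2
    mx, my = 0.5 * (x1 + x2), 0.5 * (y1 + y2)
    sxx = float(dx @ dx)
    bw = float(dx @ dy) / sxx if sxx > 0 else np.nan
    n = mx.size
    vx = float(mx @ mx) - n * float(mx.mean()) ** 2
    bb = ((float(mx @ my) - n * mx.mean() * my.mean()) / vx
          if vx > 0 else np.nan)
    return bw, bb


def _betas_no_covariates_vec(y1, y2, x1, x2, idx):
    """Vectorized closed-form betas over a (B, n) resample index matrix."""
    dx, dy = x1 - x2, y1 - y2
    mx, my = 0.5 * (x1 + x2), 0.5 * (y1 + y2)
    n = idx.shape[1]
    a_xy, a_xx = (dx * dy)[idx], (dx * dx)[idx]
    sxx = a_xx.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        bw = np.where(sxx > 0, a_xy.sum(axis=1) / sxx, np.nan)
    Mx, My = mx[idx], my[idx]
    sx, sy = Mx.sum(axis=1), My.sum(axis=1)
    sxx_m = (Mx * Mx).sum(axis=1)
    sxy_m = (Mx * My).sum(axis=1)
    denom = n * sxx_m - sx * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        bb = np.where(denom > 0, (n * sxy_m - sx * sy) / denom, np.nan)
    return bw, bb


def bootstrap_pairs(cohort: pd.DataFrame, outcome: str, predictor: str,
                    covariates: Sequence[str] = (),
                    extra_covariate_sets: Mapping[str, Sequence[str]] | None = None,
                    n_boot: int = 10_000, seed: int | None = None,
                    method: str = "reml", min_pairs: int = 10,
                    chunk: int = 512) -> BootstrapResult:
    """Cluster bootstrap of the decomposition model, resampling twin pairs.

    The base model uses ``covariates``; ``extra_covariate_sets`` maps model
    names to alternative covariate lists refit on the same resamples (for
    paired contrasts such as the before/after-SES test). All models are
    fitted on the identical set of complete pairs (intersection of required
    columns). ``n_boot=0`` returns point fits with empty replicate arrays.
    """
    models = {"base": tuple(covariates)}
    for name, cols in (extra_covariate_sets or {}).items():
        if name == "base":
            raise ValueError("'base' is reserved for the primary model")
        models[name] = tuple(cols)

    all_cols = sorted({outcome, predictor}
                      | {c for cols in models.values() for c in cols})
    df, _ = validate_pairs(cohort, all_cols)
    n = df["family_id"].nunique()

    fits = {name: fit_within_between(df, outcome, predictor, cols,
                                     method=method, min_pairs=min_pairs)
            for name, cols in models.items()}

    rng = np.random.default_rng(seed)
    reps = {name: np.full((n_boot, 2), np.nan) for name in models}
    n_failed = {name: 0 for name in models}
    if n_boot > 0:
        data = {}
        for name, cols in models.items():
            y, X = _pair_arrays(df, outcome, predictor, cols)
            data[name] = (y[0::2], y[1::2], X[0::2], X[1::2], len(cols))
        for start in range(0, n_boot, chunk):
            B = min(chunk, n_boot - start)
            idx = rng.integers(0, n, size=(B, n))
            for name, (y1, y2, X1, X2, ncov) in data.items():
                if ncov == 0:
                    bw, bb = _betas_no_covariates_vec(
                        y1, y2, X1[:, 0], X2[:, 0], idx)
                    reps[name][start:start + B, 0] = bw
                    reps[name][start:start + B, 1] = bb
                else:
                    for b in range(B):
                        take = idx[b]
                        reps[name][start + b] = _fit_betas_general(
                            y1[take], y2[take], X1[take], X2[take], method)
        for name in models:
            n_failed[name] = int(np.isnan(reps[name][:, 0]).sum())
            if n_boot and n_failed[name] > 0.01 * n_boot:
                warnings.warn(
                    f"model '{name}': {n_failed[name]}/{n_boot} bootstrap "
                    "replicates failed", RuntimeWarning)
    return BootstrapResult(n_boot=n_boot, seed=seed, n_pairs=n, fits=fits,
                           replicates=reps, n_failed=n_failed)


def _fit_betas_general(y1, y2, X1, X2, method: str):
    """Refit the full pair REML model on one replicate; betas only."""
    n = y1.size
    y = np.empty(2 * n)
    y[0::2], y[1::2] = y1, y2
    x1, x2 = X1[:, 0], X2[:, 0]
    fam_mean = 0.5 * (x1 + x2)
    D = np.empty((2 * n, 3 + X1.shape[1] - 1))
    D[:, 0] = 1.0
    D[0::2, 1], D[1::2, 1] = x1 - fam_mean, x2 - fam_mean
    D[0::2, 2] = D[1::2, 2] = fam_mean
    D[0::2, 3:], D[1::2, 3:] = X1[:, 1:], X2[:, 1:]
    try:
        beta = _reml_pairs(D, y, method=method)[0]
        return beta[1], beta[2]
    except np.linalg.LinAlgError:
        return np.nan, np.nan


@dataclass
class DiffTestResult:
    diff: float
    diff_sd: float
    z: float
    p: float


def diff_test(boot: BootstrapResult, model: str = "base") -> DiffTestResult:
    """Test beta_b - beta_w against zero using the bootstrap difference SD.

    z is the full-sample coefficient difference divided by the standard
    deviation of the replicate-wise (beta_b - beta_w) distribution; two-sided
    p from the standard normal.
    """
    fit = boot.fits[model]
    reps = boot.replicates[model]
    d = reps[:, 1] - reps[:, 0]
    d = d[np.isfinite(d)]
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("degenerate bootstrap difference distribution (sd = 0)")
    diff = fit.beta_b - fit.beta_w
    z = diff / sd
    return DiffTestResult(diff=float(diff), diff_sd=sd, z=float(z),
                          p=float(2.0 * stats.norm.sf(abs(z))))


@dataclass
class AttenuationResult:
    pct: float
    ci_low: float
    ci_high: float
    defined: bool


def attenuation(boot: BootstrapResult, model: str = "base",
                tol: float = 1e-8) -> AttenuationResult:
    """Percentage change 100 (bB - bW)/bB with a percentile CI.

    Flagged undefined (NaN, ``defined=False``) when |beta_b| falls below
    ``tol`` — a near-zero between-family coefficient makes the ratio
    meaningless.
    """
    fit = boot.fits[model]
    if abs(fit.beta_b) < tol:
        return AttenuationResult(float("nan"), float("nan"), float("nan"), False)
    pct = 100.0 * (fit.beta_b - fit.beta_w) / fit.beta_b
    reps = boot.replicates[model]
    with np.errstate(invalid="ignore", divide="ignore"):
        rep_pct = np.where(np.abs(reps[:, 1]) < tol, np.nan,
                           100.0 * (reps[:, 1] - reps[:, 0]) / reps[:, 1])
    if np.isfinite(rep_pct).sum() >= 2:
        lo, hi = np.nanpercentile(rep_pct, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return AttenuationResult(float(pct), float(lo), float(hi), True)


@dataclass
class ShiftTestResult:
    delta: float
    delta_sd: float
    z: float
    p: float
    ci_low: float
    ci_high: float


def covariate_shift_test(boot: BootstrapResult, raw: str = "base",
                         adjusted: str = "adjusted") -> ShiftTestResult:
    """Paired test of the between-family coefficient before vs after adjustment.

    Both models must live in the same BootstrapResult (hence share resamples
    and the fitted pair set). delta = beta_b(raw) - beta_b(adjusted); z uses
    the SD of the paired replicate-wise delta, CI its percentiles.
    """
    for name in (raw, adjusted):
        if name not in boot.replicates:
            raise ValueError(
                f"model '{name}' not in this bootstrap run — the shift test "
                "requires paired replicates from a single bootstrap_pairs call")
    d = boot.replicates[raw][:, 1] - boot.replicates[adjusted][:, 1]
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ValueError("not enough finite paired replicates")
    sd = float(np.std(d, ddof=1))
    delta = boot.fits[raw].beta_b - boot.fits[adjusted].beta_b
    if sd == 0.0:
        raise ValueError("degenerate paired difference distribution (sd = 0)")
    z = delta / sd
    lo, hi = np.percentile(d, [2.5, 97.5])
    return ShiftTestResult(delta=float(delta), delta_sd=sd, z=float(z),
                           p=float(2.0 * stats.norm.sf(abs(z))),
                           ci_low=float(lo), ci_high=float(hi))


@dataclass
class BHResult:
    threshold: float
    significant: np.ndarray
    n_discoveries: int
    alpha: float


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> BHResult:
    """Benjamini-Hochberg step-up rule on raw p-values.

    The corrected threshold is the largest order statistic p(k) satisfying
    p(k) <= (k/m) alpha; every p at or below it is a discovery. With no such
    k the threshold is NaN and nothing is flagged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    ps = np.sort(p)
    ranks = np.arange(1, m + 1)
    ok = ps <= ranks / m * alpha
    if not ok.any():
        return BHResult(float("nan"), np.zeros(m, dtype=bool), 0, alpha)
    thresh = float(ps[np.flatnonzero(ok)[-1]])
    sig = p <= thresh
    return BHResult(thresh, sig, int(sig.sum()), alpha)
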