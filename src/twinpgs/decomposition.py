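"""Within- vs between-family decomposition of a polygenic-score effect.

The model is a Gaussian random-intercept regression on 2-member family
clusters (DZ twin pairs):

    Y_ij = a0 + bW (GPS_ij - GPSbar_j) + bB GPSbar_j + c'x_ij + g_j + e_ij,
    g_j ~ N(0, sigma_gamma^2),   e_ij ~ N(0, sigma_eps^2),

where GPSbar_j is the family-mean score. bW (within) is identified purely by
co-twin differences and is therefore free of shared-environment, passive
gene-environment-correlation, stratification and assortative-mating
confounding; bB (between) absorbs all of those family-level pathways. The
intraclass correlation ICC = sigma_gamma^2 / (sigma_gamma^2 + sigma_eps^2)
weights the two into the population-level total effect
bW (1 - ICC) + bB ICC.

Estimation is restricted maximum likelihood (REML), profiled down to a 1-D
search over the variance ratio lambda = sigma_gamma^2 / sigma_eps^2. For
pairs, rotating each cluster onto its sum and difference contrasts makes the
covariance diagonal with two strata (relative variances 1 + 2 lambda and 1),
so each profile evaluation is a closed-form weighted least-squares solve.
With no extra covariates the strata decouple and the fixed effects reduce
exactly to two ordinary regressions: bW is the through-origin slope of
co-twin outcome differences on score differences, bB the slope of family
means on family means.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "WithinBetweenRegression", "DecompositionFit", "build_design",
    "fit_within_between", "icc", "total_effect", "validate_pairs",
]

_SQRT2 = np.sqrt(2.0)


class PairStructureError(ValueError):
    """Raised when the cohort does not consist of complete 2-member families."""


def validate_pairs(cohort: pd.DataFrame, columns: Sequence[str],
                   strict: bool = False) -> tuple[pd.DataFrame, int]:
    """Keep complete 2-member families with no missing values in ``columns``.

    Returns the validated frame (sorted by family then member) and the number
    of excluded families. ``strict=True`` raises instead of excluding.
    """
    required = list(dict.fromkeys(["family_id", "member", *columns]))
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort is missing columns: {missing}")
    df = cohort.loc[:, required].dropna()
    counts = df.groupby("family_id")["member"].agg(["size", "nunique"])
    good = counts.index[(counts["size"] == 2) & (counts["nunique"] == 2)]
    n_excluded = cohort["family_id"].nunique() - good.size
    if n_excluded and strict:
        raise PairStructureError(
            f"{n_excluded} families lack exactly 2 complete members")
    df = df[df["family_id"].isin(good)]
    df = df.sort_values(["family_id", "member"], kind="stable").reset_index(drop=True)
    return df, int(n_excluded)


def build_design(cohort: pd.DataFrame, predictor: str,
                 strict: bool = False) -> pd.DataFrame:
    """Append group-mean-centered columns for ``predictor``.

    Adds ``<predictor>_within`` (deviation from the family mean, summing to
    zero within every family) and ``<predictor>_between`` (the family mean,
    constant within family). Incomplete families are excluded (or rejected
    when ``strict``).
    """
    extra = [c for c in cohort.columns if c not in ("family_id", "member")]
    df, _ = validate_pairs(cohort, extra, strict=strict)
    fam_mean = df.groupby("family_id")[predictor].transform("mean")
    df[f"{predictor}_within"] = df[predictor] - fam_mean
    df[f"{predictor}_between"] = fam_mean
    return df


@dataclass
class DecompositionFit:
    """Fitted within/between random-intercept model."""

    outcome: str
    predictor: str
    covariates: tuple
    alpha0: float
    beta_w: float
    beta_b: float
    covariate_coefs: dict
    sigma_gamma2: float
    sigma_eps2: float
    icc: float
    total_effect: float
    se: dict
    pvalues: dict
    n_pairs: int
    n_excluded: int
    loglik: float
    method: str
    converged: bool
    boundary: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def summary(self) -> str:
        lines = [
            f"Within/between decomposition: {self.outcome} ~ {self.predictor}"
            + (f" + {', '.join(self.covariates)}" if self.covariates else ""),
            f"  n_pairs = {self.n_pairs} (excluded families: {self.n_excluded})",
            f"  beta_within  = {self.beta_w:+.4f}  (se {self.se['beta_w']:.4f},"
            f" p {self.pvalues['beta_w']:.3g})",
            f"  beta_between = {self.beta_b:+.4f}  (se {self.se['beta_b']:.4f},"
            f" p {self.pvalues['beta_b']:.3g})",
            f"  sigma_gamma2 = {self.sigma_gamma2:.4f}, sigma_eps2 = "
            f"{self.sigma_eps2:.4f}, ICC = {self.icc:.4f}",
            f"  total effect = {self.total_effect:+.4f}  [{self.method}"
            + (", boundary" if self.boundary else "") + "]",
        ]
        return "\n".join(lines)


class WithinBetweenRegression(BaseEstimator):
    """Random-intercept regression separating within- and between-family effects.

    Parameters
    ----------
    method : {"reml", "ml"}
        Variance-component estimator. REML (default) profiles the restricted
        likelihood over the variance ratio; ML uses the full likelihood.
    ratio_max : float
        Upper bound of the search range for lambda = sigma_gamma^2/sigma_eps^2.
    min_pairs : int
        Minimum number of complete pairs required to fit.

    The design matrix ``X`` passed to :meth:`fit` has the predictor in its
    first column; any further columns enter as fixed-effect covariates.
    ``groups`` labels the 2-member families.

    Attributes (after fit)
    ----------------------
    intercept_, beta_w_, beta_b_ : float
    coef_ : ndarray — full fixed-effect vector (intercept, within, between,
        covariates).
    covariate_coefs_ : ndarray — covariate block of ``coef_``.
    sigma_gamma2_, sigma_eps2_, icc_, total_effect_ : float
    bse_, pvalues_ : ndarray aligned with ``coef_`` (Wald, normal reference).
    loglik_ : float; n_pairs_ : int; converged_, boundary_ : bool
    """

    def __init__(self, method: str = "reml", ratio_max: float = 1e6,
                 min_pairs: int = 10):
        self.method = method
        self.ratio_max = ratio_max
        self.min_pairs = min_pairs

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if X.shape[0] != y.shape[0] or groups.shape[0] != y.shape[0]:
            raise ValueError("X, y and groups must have equal length")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in X or y")
        if self.method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")

        order = np.argsort(groups, kind="stable")
        g = groups[order]
        if g.size % 2 or np.any(g[0::2] != g[1::2]):
            raise PairStructureError("every family must have exactly 2 members")
        n_pairs = g.size // 2
        if n_pairs < self.min_pairs:
            raise ValueError(f"need at least {self.min_pairs} pairs, got {n_pairs}")
        if np.var(y) == 0:
            raise ValueError("outcome has zero variance")

        Xo, yo = X[order], y[order]
        x = Xo[:, 0]
        fam_mean = np.repeat(0.5 * (x[0::2] + x[1::2]), 2)
        D = np.column_stack([np.ones_like(y), x - fam_mean, fam_mean, Xo[:, 1:]])

        res = _reml_pairs(D, yo, method=self.method, ratio_max=self.ratio_max)
        (self.coef_, self.bse_, self.pvalues_, self.sigma_gamma2_,
         self.sigma_eps2_, self.loglik_, self.converged_, self.boundary_) = res
        self.intercept_ = float(self.coef_[0])
        self.beta_w_ = float(self.coef_[1])
        self.beta_b_ = float(self.coef_[2])
        self.covariate_coefs_ = self.coef_[3:]
        tot = self.sigma_gamma2_ + self.sigma_eps2_
        self.icc_ = float(self.sigma_gamma2_ / tot) if tot > 0 else np.nan
        self.total_effect_ = float(
            self.beta_w_ * (1.0 - self.icc_) + self.beta_b_ * self.icc_)
        self.n_pairs_ = int(n_pairs)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, groups):
        """Fixed-effect prediction using within/between columns built from X."""
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        groups = np.asarray(groups)
        x = X[:, 0]
        df = pd.DataFrame({"g": groups, "x": x})
        fam_mean = df.groupby("g")["x"].transform("mean").to_numpy()
        D = np.column_stack([np.ones(x.size), x - fam_mean, fam_mean, X[:, 1:]])
        return D @ self.coef_


def _reml_pairs(D: np.ndarray, y: np.ndarray, method: str = "reml",
                ratio_max: float = 1e6):
    """Profiled (RE)ML for the pair random-intercept model.

    Rows of ``D``/``y`` are ordered pairwise. Rotation onto per-pair sums and
    differences (each scaled by 1/sqrt(2)) yields independent observations in
    two variance strata: Var = sigma_eps^2 (1 + 2 lambda) for sums and
    sigma_eps^2 for differences. The criterion is minimized over lambda on
    [0, ratio_max] by a coarse log-spaced grid followed by bounded Brent
    refinement; lambda = 0 (no family variance) is a legal boundary solution.
    """
    n, p = D.shape
    Ds, Dd = (D[0::2] + D[1::2]) / _SQRT2, (D[0::2] - D[1::2]) / _SQRT2
    ys, yd = (y[0::2] + y[1::2]) / _SQRT2, (y[0::2] - y[1::2]) / _SQRT2
    Gs, Gd = Ds.T @ Ds, Dd.T @ Dd
    hs, hd = Ds.T @ ys, Dd.T @ yd
    sys_, syd = float(ys @ ys), float(yd @ yd)
    n_s = ys.size
    dof = n - p if method == "reml" else n

    def solve(lam):
        w = 1.0 / (1.0 + 2.0 * lam)
        G = w * Gs + Gd
        beta = np.linalg.solve(G, w * hs + hd)
        rss = (w * (sys_ - 2.0 * beta @ hs + beta @ Gs @ beta)
               + (syd - 2.0 * beta @ hd + beta @ Gd @ beta))
        return beta, G, max(rss, 1e-300)

    def crit(lam):
        beta, G, rss = solve(lam)
        val = dof * np.log(rss / dof) + n_s * np.log1p(2.0 * lam)
        if method == "reml":
            val += np.linalg.slogdet(G)[1]
        return val

    grid = np.concatenate([[0.0], np.logspace(-6, np.log10(ratio_max), 40)])
    vals = [crit(l) for l in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    converged = True
    if hi > lo:
        r = optimize.minimize_scalar(crit, bounds=(lo, hi), method="bounded",
                                     options={"xatol": 1e-10})
        lam = float(r.x) if r.fun <= vals[k] else float(grid[k])
        converged = bool(r.success)
    else:
        lam = float(grid[k])
    if crit(0.0) <= crit(lam):
        lam = 0.0
    boundary = lam < 1e-8

    beta, G, rss = solve(lam)
    sigma_eps2 = rss / dof
    sigma_gamma2 = lam * sigma_eps2
    cov = sigma_eps2 * np.linalg.inv(G)
    bse = np.sqrt(np.diag(cov))
    z = np.divide(beta, bse, out=np.zeros_like(beta), where=bse > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    loglik = -0.5 * (crit(lam) + dof * (1.0 + np.log(2.0 * np.pi)))
    return beta, bse, pvals, float(sigma_gamma2), float(sigma_eps2), \
        float(loglik), converged, boundary


def fit_within_between(cohort: pd.DataFrame, outcome: str, predictor: str,
                       covariates: Sequence[str] = (), method: str = "reml",
                       min_pairs: int = 10, strict: bool = False,
                       ) -> DecompositionFit:
    """Fit the within/between random-intercept model on a long-format cohort.

    Families without exactly two complete members are excluded (``strict``
    raises instead). Covariates enter as individual-level fixed effects;
    family-constant covariates load on the between part by construction.
    """
    covariates = tuple(covariates)
    if len({outcome, predictor, *covariates}) != 2 + len(covariates):
        raise ValueError("outcome, predictor and covariates must be distinct "
                         "columns")
    cols = [outcome, predictor, *covariates]
    df, n_excluded = validate_pairs(cohort, cols, strict=strict)
    X = df[[predictor, *covariates]].to_numpy(dtype=float)
    est = WithinBetweenRegression(method=method, min_pairs=min_pairs)
    est.fit(X, df[outcome].to_numpy(dtype=float), df["family_id"].to_numpy())
    names = ["alpha0", "beta_w", "beta_b", *covariates]
    se = dict(zip(names, est.bse_.tolist()))
    pv = dict(zip(names, est.pvalues_.tolist()))
    return DecompositionFit(
        outcome=outcome, predictor=predictor, covariates=covariates,
        alpha0=est.intercept_, beta_w=est.beta_w_, beta_b=est.beta_b_,
        covariate_coefs=dict(zip(covariates, est.covariate_coefs_.tolist())),
        sigma_gamma2=est.sigma_gamma2_, sigma_eps2=est.sigma_eps2_,
        icc=est.icc_, total_effect=est.total_effect_, se=se, pvalues=pv,
        n_pairs=est.n_pairs_, n_excluded=n_excluded, loglik=est.loglik_,
        method=method, converged=est.converged_, boundary=est.boundary_)


def icc(fit: DecompositionFit) -> float:
    """Intraclass correlation sigma_gamma^2 / (sigma_gamma^2 + sigma_eps^2).

    Returns NaN when both variance components are zero (undefined).
    """
    tot = fit.sigma_gamma2 + fit.sigma_eps2
    if tot <= 0:
        return float("nan")
    return fit.sigma_gamma2 / tot


def total_effect(beta_w: float, beta_b: float, icc: float) -> float:
    """ICC-weighted total effect bW (1 - ICC) + bB ICC; bounded by the betas."""
    if not (0.0 <= icc <= 1.0) or not np.isfinite(icc):
        raise ValueError("icc must lie in [0, 1]")
    return beta_w * (1.0 - icc) + beta_b * icc
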