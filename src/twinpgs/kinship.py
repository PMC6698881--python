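"""Genetic relationship matrix (GRM) sensitivity model.

To check that unmodelled relatedness between families does not drive the
between-family coefficient, the fixed effects of the within/between
decomposition are refit with a genome-wide random effect g ~ N(0, A sg^2),
where A is the GRM with entries

    A_mn = (1/N) sum_i (x_im - 2 p_i)(x_in - 2 p_i) / (2 p_i (1 - p_i)),

x_im the effect-allele dosage of individual m at variant i and p_i the
allele frequency. Estimation is REML after rotating onto the eigenbasis of
A, which diagonalizes the covariance so the variance ratio
lambda = sg^2/se^2 can be profiled by a 1-D search with closed-form weighted
least squares at each step.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .decomposition import validate_pairs

__all__ = ["GRM", "GRMFit", "compute_grm", "KinshipRegression", "fit_grm_lmm"]


@dataclass
class GRM:
    """Symmetric genetic relationship matrix with its individual ids."""

    ids: list
    matrix: np.ndarray
    n_variants: int
    n_excluded: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.ids), len(self.ids)):
            raise ValueError("GRM dimensions must match the id list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    def reindex(self, ids: Sequence) -> "GRM":
        pos = {v: i for i, v in enumerate(self.ids)}
        missing = [v for v in ids if v not in pos]
        if missing:
            raise KeyError(f"{len(missing)} individuals absent from the GRM "
                           f"(first: {missing[0]!r})")
        take = np.asarray([pos[v] for v in ids])
        return GRM(list(ids), self.matrix[np.ix_(take, take)],
                   self.n_variants, self.n_excluded)


def compute_grm(genotypes, freqs=None, ids=None) -> GRM:
    """GRM from an individuals-by-variants dosage matrix.

    Frequencies default to the sample estimate p_i = mean(x_i)/2 (the GCTA
    convention); monomorphic variants (p outside (0,1)) are excluded with a
    count. Columns are standardized to (x - 2p)/sqrt(2 p (1-p)) and A is the
    averaged cross-product Z Z' / N.
    """
    if isinstance(genotypes, pd.DataFrame):
        X = genotypes.to_numpy(dtype=float)
        if ids is None:
            ids = list(genotypes.index)
    else:
        X = np.asarray(genotypes, dtype=float)
        if ids is None:
            ids = list(range(X.shape[0]))
    if X.ndim != 2:
        raise ValueError("genotypes must be 2-D (individuals x variants)")
    p = X.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    if p.size != X.shape[1]:
        raise ValueError("one frequency per variant required")
    keep = (p > 0.0) & (p < 1.0)
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("no polymorphic variants usable for the GRM")
    Xk, pk = X[:, keep], p[keep]
    Z = (Xk - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    A = Z @ Z.T / keep.sum()
    return GRM(list(ids), A, int(keep.sum()), n_excluded)


@dataclass
class GRMFit:
    """Fixed effects of the decomposition refit under a GRM random effect."""

    outcome: str
    predictor: str
    covariates: tuple
    alpha: float
    beta_w: float
    beta_b: float
    covariate_coefs: dict
    sigma_g2: float
    sigma_eps2: float
    se: dict
    pvalues: dict
    n: int
    loglik: float
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


class KinshipRegression(BaseEstimator):
    """Linear mixed model y = Xb + g + e with g ~ N(0, A sg^2).

    ``X`` passed to :meth:`fit` has the predictor in its first column
    (expanded internally into within/between columns using ``groups``);
    remaining columns are fixed-effect covariates. ``A`` is the relationship
    matrix aligned to the rows of X. Negative eigenvalues of A (numerical)
    are clipped at zero with a warning.
    """

    def __init__(self, ratio_max: float = 1e6):
        self.ratio_max = ratio_max

    def fit(self, X, y, groups, A):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        A = np.asarray(A, dtype=float)
        n = y.size
        if X.shape[0] != n or groups.size != n or A.shape != (n, n):
            raise ValueError("X, y, groups and A must be conformable")

        x = X[:, 0]
        fam_mean = pd.Series(x).groupby(pd.Series(groups)).transform("mean") \
            .to_numpy()
        D = np.column_stack([np.ones(n), x - fam_mean, fam_mean, X[:, 1:]])
        p = D.shape[1]

        d, U = np.linalg.eigh(A)
        if d.min() < -1e-8:
            warnings.warn("negative GRM eigenvalues clipped at zero",
                          RuntimeWarning)
        d = np.clip(d, 0.0, None)
        yt, Dt = U.T @ y, U.T @ D

        def solve(lam):
            w = 1.0 / (1.0 + lam * d)
            Dw = Dt * w[:, None]
            G = Dw.T @ Dt
            beta = np.linalg.solve(G, Dw.T @ yt)
            r = yt - Dt @ beta
            rss = float(r @ (w * r))
            return beta, G, max(rss, 1e-300), w

        dof = n - p

        def crit(lam):
            beta, G, rss, w = solve(lam)
            val = dof * np.log(rss / dof) - np.log(w).sum()
            val += np.linalg.slogdet(G)[1]
            return val

        grid = np.concatenate([[0.0],
                               np.logspace(-6, np.log10(self.ratio_max), 40)])
        vals = [crit(l) for l in grid]
        k = int(np.argmin(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
        converged = True
        if hi > lo:
            r = optimize.minimize_scalar(crit, bounds=(lo, hi),
                                         method="bounded",
                                         options={"xatol": 1e-10})
            lam = float(r.x) if r.fun <= vals[k] else float(grid[k])
            converged = bool(r.success)
        else:
            lam = float(grid[k])
        if crit(0.0) <= crit(lam):
            lam = 0.0

        beta, G, rss, w = solve(lam)
        sigma_eps2 = rss / dof
        cov = sigma_eps2 * np.linalg.inv(G)
        self.coef_ = beta
        self.bse_ = np.sqrt(np.diag(cov))
        zstat = np.divide(beta, self.bse_, out=np.zeros_like(beta),
                          where=self.bse_ > 0)
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(zstat))
        self.intercept_ = float(beta[0])
        self.beta_w_ = float(beta[1])
        self.beta_b_ = float(beta[2])
        self.covariate_coefs_ = beta[3:]
        self.sigma_eps2_ = float(sigma_eps2)
        self.sigma_g2_ = float(lam * sigma_eps2)
        self.loglik_ = -0.5 * (crit(lam) + dof * (1.0 + np.log(2.0 * np.pi)))
        self.converged_ = converged
        self.boundary_ = lam < 1e-8
        self.n_ = int(n)
        return self


def fit_grm_lmm(cohort: pd.DataFrame, grm: GRM, outcome: str, predictor: str,
                covariates: Sequence[str] = ()) -> GRMFit:
    """Refit the decomposition fixed effects with the GRM random effect.

    Individuals are matched to the GRM by the cohort's ``iid`` column (or
    ``family_id``/``member`` composite when absent); a cohort individual
    missing from the GRM is an error.
    """
    covariates = tuple(covariates)
    cols = [outcome, predictor, *covariates]
    has_iid = "iid" in cohort.columns
    df, _ = validate_pairs(cohort, cols + (["iid"] if has_iid else []))
    iids = (df["iid"] if has_iid
            else df["family_id"].astype(str) + "_" + df["member"].astype(str))
    sub = grm.reindex(list(iids))
    est = KinshipRegression()
    est.fit(df[[predictor, *covariates]].to_numpy(dtype=float),
            df[outcome].to_numpy(dtype=float),
            df["family_id"].to_numpy(), sub.matrix)
    names = ["alpha", "beta_w", "beta_b", *covariates]
    return GRMFit(
        outcome=outcome, predictor=predictor, covariates=covariates,
        alpha=est.intercept_, beta_w=est.beta_w_, beta_b=est.beta_b_,
        covariate_coefs=dict(zip(covariates, est.covariate_coefs_.tolist())),
        sigma_g2=est.sigma_g2_, sigma_eps2=est.sigma_eps2_,
        se=dict(zip(names, est.bse_.tolist())),
        pvalues=dict(zip(names, est.pvalues_.tolist())),
        n=est.n_, loglik=est.loglik_, converged=est.converged_,
        boundary=est.boundary_)
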