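"""Polygenic scoring and covariate residualization.

A polygenic score is the weighted sum of effect-allele dosages across
variants, with weights taken from an external association study. Scores and
outcomes are routinely adjusted for nuisance covariates (principal
components, genotyping chip/plate, sex, age) with the regression method:
ordinary-least-squares residuals, z-standardized to mean 0 and SD 1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "score_individuals", "residualize_standardize", "preprocess_outcome",
    "ScoringReport",
]

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("G", "C"))}


@dataclass
class ScoringReport:
    n_variants_used: int
    n_missing: int        # weight variants absent from the genotypes
    n_flipped: int        # scored on the other allele via dosage 2 - x
    n_mismatched: int     # dropped: alleles irreconcilable or strand-ambiguous


def score_individuals(genotypes: pd.DataFrame, weights: pd.DataFrame,
                      genotype_alleles: pd.DataFrame | None = None,
                      return_report: bool = False):
    """Weighted allele-dosage sum per individual.

    Parameters
    ----------
    genotypes : DataFrame, individuals x variants, effect-allele dosages in
        [0, 2].
    weights : DataFrame with columns ``variant_id``, ``effect_allele``,
        ``weight``.
    genotype_alleles : optional DataFrame with columns ``variant_id``,
        ``counted_allele``, ``other_allele`` describing which allele the
        dosage counts. When absent the counted allele is assumed to be the
        weight's effect allele. A weight on the other allele is flipped
        (dosage 2 - x); strand-ambiguous A/T and G/C variants that require a
        flip are dropped with a warning.

    Scoring uses the intersection of weight and genotype variants; an empty
    intersection is an error.
    """
    _validate_weights(weights)
    w = weights.set_index("variant_id")
    shared = [v for v in w.index if v in genotypes.columns]
    n_missing = len(w.index) - len(shared)
    if not shared:
        raise ValueError("no overlap between weight and genotype variants")

    use = []
    flip = []
    n_flipped = n_mismatch = 0
    alleles = (genotype_alleles.set_index("variant_id")
               if genotype_alleles is not None else None)
    for v in shared:
        eff = str(w.at[v, "effect_allele"])
        if alleles is None or v not in alleles.index:
            use.append(v)
            flip.append(False)
            continue
        counted = str(alleles.at[v, "counted_allele"])
        other = str(alleles.at[v, "other_allele"])
        if eff == counted:
            use.append(v)
            flip.append(False)
        elif eff == other:
            if frozenset((counted, other)) in _AMBIGUOUS:
                n_mismatch += 1
            else:
                use.append(v)
                flip.append(True)
                n_flipped += 1
        else:
            n_mismatch += 1
    if n_mismatch:
        warnings.warn(f"dropped {n_mismatch} variants with irreconcilable "
                      "or strand-ambiguous alleles", RuntimeWarning)
    if not use:
        raise ValueError("no scorable variants after allele matching")

    G = genotypes[use].to_numpy(dtype=float)
    if np.nanmin(G) < 0 or np.nanmax(G) > 2:
        raise ValueError("dosages must lie in [0, 2]")
    flip = np.asarray(flip)
    if flip.any():
        G = G.copy()
        G[:, flip] = 2.0 - G[:, flip]
    scores = pd.Series(G @ w.loc[use, "weight"].to_numpy(dtype=float),
                       index=genotypes.index, name="score")
    if return_report:
        return scores, ScoringReport(len(use), n_missing, n_flipped, n_mismatch)
    return scores


def _validate_weights(weights: pd.DataFrame) -> None:
    need = {"variant_id", "effect_allele", "weight"}
    if not need.issubset(weights.columns):
        raise ValueError(f"weights table needs columns {sorted(need)}")
    if weights["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in weights table")
    if not np.isfinite(weights["weight"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite weights")


def residualize_standardize(values, covariates=None) -> np.ndarray:
    """OLS-residualize ``values`` on covariates (plus intercept), then z-score.

    Categorical covariate columns are one-hot expanded. Collinear covariate
    columns are tolerated (minimum-norm solve) with a warning; residuals are
    unaffected by the choice of solution. Standardization uses the n-1
    denominator. Zero residual variance is an error — the covariates explain
    the variable exactly.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        y = y.ravel()
    if y.size < 2:
        raise ValueError("need at least 2 values")
    X = _covariate_matrix(covariates, y.size)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient covariates; collinear columns have no "
                      "effect on the residuals", RuntimeWarning)
    resid = y - X @ beta
    sd = np.std(resid, ddof=1)
    if sd < 1e-12 * max(1.0, np.std(y, ddof=1)):
        raise ValueError("zero residual variance: covariates explain the "
                         "variable exactly")
    return (resid - resid.mean()) / sd


def _covariate_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, pd.DataFrame):
        C = pd.get_dummies(covariates, drop_first=True, dtype=float)
        C = C.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows must match the number of values")
    return np.column_stack([np.ones(n), C])


def preprocess_outcome(outcome, sex, age) -> np.ndarray:
    """Adjust an outcome for sex and age; z-standardized residuals."""
    C = np.column_stack([np.asarray(sex, dtype=float),
                         np.asarray(age, dtype=float)])
    return residualize_standardize(outcome, C)
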