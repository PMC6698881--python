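"""Within/between random-intercept model: oracles, invariances, recovery."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given
from hypothesis import strategies as st

from twinpgs.decomposition import (DecompositionFit, PairStructureError,
                                   WithinBetweenRegression, build_design,
                                   fit_within_between, icc, total_effect,
                                   validate_pairs)
from twinpgs.simulate import SimulationConfig, generate_cohort

from conftest import make_pair_frame


def paired_ols(x, y):
    """Closed-form oracle: difference regression and mean regression."""
    dx, dy = x[:, 0] - x[:, 1], y[:, 0] - y[:, 1]
    bw = (dx @ dy) / (dx @ dx)
    mx, my = x.mean(axis=1), y.mean(axis=1)
    bb = np.cov(mx, my, ddof=1)[0, 1] / np.var(mx, ddof=1)
    return bw, bb


def _random_pair_data(rng, n=150):
    x = rng.normal(size=(n, 2)) + 0.8 * rng.normal(size=(n, 1))
    y = (0.4 * x + rng.normal(size=(n, 1))
         + 0.7 * rng.normal(size=(n, 2)))
    return x, y


# ------------------------------------------------------------- build_design

def test_build_design_arithmetic():
    df = make_pair_frame(np.array([[1.0, 3.0]]), np.zeros((1, 2)))
    out = build_design(pd.concat([df] * 12, ignore_index=True)
                       .assign(family_id=np.repeat(np.arange(12), 2)), "gps")
    assert np.allclose(out["gps_within"], np.tile([-1.0, 1.0], 12))
    assert np.allclose(out["gps_between"], 2.0)


def test_build_design_identical_scores_zero_within():
    df = make_pair_frame(np.full((15, 2), 0.7), np.zeros((15, 2)))
    out = build_design(df, "gps")
    assert np.allclose(out["gps_within"], 0.0)


@given(st.integers(0, 2**31 - 1))
def test_within_column_sums_to_zero_per_family(seed):
    rng = np.random.default_rng(seed)
    df = make_pair_frame(rng.normal(size=(20, 2)), rng.normal(size=(20, 2)))
    out = build_design(df, "gps")
    sums = out.groupby("family_id")["gps_within"].sum()
    assert np.allclose(sums, 0.0)
    assert (out.groupby("family_id")["gps_between"].nunique() == 1).all()


def test_validate_pairs_excludes_incomplete():
    df = make_pair_frame(np.ones((12, 2)), np.ones((12, 2)))
    df = df.drop(index=[1])  # family 0 loses member 2
    clean, n_excl = validate_pairs(df, ["gps"])
    assert n_excl == 1
    assert clean["family_id"].nunique() == 11
    with pytest.raises(PairStructureError):
        validate_pairs(df, ["gps"], strict=True)


# ---------------------------------------------------------------- exact fit

def test_reml_equals_paired_ols_closed_form(rng):
    for _ in range(20):
        x, y = _random_pair_data(rng)
        fit = fit_within_between(make_pair_frame(x, y), "outcome", "gps")
        bw, bb = paired_ols(x, y)
        assert fit.beta_w == pytest.approx(bw, abs=1e-6)
        assert fit.beta_b == pytest.approx(bb, abs=1e-6)


def test_agrees_with_statsmodels_mixedlm(small_cohort):
    t = small_cohort.table
    d = build_design(t, "gps")
    fit = fit_within_between(t, "outcome", "gps", covariates=("ses",))
    m = smf.mixedlm("outcome ~ gps_within + gps_between + ses", d,
                    groups=d["family_id"]).fit(reml=True)
    assert fit.beta_w == pytest.approx(m.params["gps_within"], abs=1e-5)
    assert fit.beta_b == pytest.approx(m.params["gps_between"], abs=1e-5)
    assert fit.covariate_coefs["ses"] == pytest.approx(m.params["ses"], abs=1e-5)
    assert fit.sigma_gamma2 == pytest.approx(float(m.cov_re.iloc[0, 0]),
                                             abs=1e-4)
    assert fit.sigma_eps2 == pytest.approx(m.scale, abs=1e-4)
    assert fit.se["beta_w"] == pytest.approx(m.bse["gps_within"], rel=1e-4)


def test_pure_within_signal_boundary_fit(rng):
    # Y differences driven only by GPS differences; no family variance
    n = 2000
    x = rng.normal(size=(n, 2))
    w = x - x.mean(axis=1, keepdims=True)
    y = 0.4 * w + 0.1 * rng.normal(size=(n, 2))
    fit = fit_within_between(make_pair_frame(x, y), "outcome", "gps")
    assert fit.beta_w == pytest.approx(0.4, abs=0.02)
    assert fit.beta_b == pytest.approx(0.0, abs=0.02)
    assert fit.sigma_gamma2 < 0.01
    assert fit.icc < 0.1


def test_no_family_confound_betas_agree():
    cfg = SimulationConfig(n_families=2500, n_loci=300, beta_direct=0.3,
                           beta_nurture=0.0, c_shared=0.0, strat_shift=0.0,
                           sigma_e=0.7, seed=55)
    fit = fit_within_between(generate_cohort(cfg).table, "outcome", "gps")
    assert fit.beta_w == pytest.approx(0.3, abs=0.06)
    assert fit.beta_b == pytest.approx(0.3, abs=0.06)


# -------------------------------------------------------------- invariances

def test_outcome_shift_changes_only_intercept(rng):
    x, y = _random_pair_data(rng)
    df1 = make_pair_frame(x, y)
    df2 = make_pair_frame(x, y + 5.0)
    f1 = fit_within_between(df1, "outcome", "gps")
    f2 = fit_within_between(df2, "outcome", "gps")
    assert f2.alpha0 == pytest.approx(f1.alpha0 + 5.0, abs=1e-8)
    assert f2.beta_w == pytest.approx(f1.beta_w, abs=1e-8)
    assert f2.beta_b == pytest.approx(f1.beta_b, abs=1e-8)
    assert f2.sigma_gamma2 == pytest.approx(f1.sigma_gamma2, abs=1e-6)


def test_predictor_scaling_inverse_on_betas(rng):
    x, y = _random_pair_data(rng)
    f1 = fit_within_between(make_pair_frame(x, y), "outcome", "gps")
    f2 = fit_within_between(make_pair_frame(3.0 * x, y), "outcome", "gps")
    assert f2.beta_w == pytest.approx(f1.beta_w / 3.0, abs=1e-8)
    assert f2.beta_b == pytest.approx(f1.beta_b / 3.0, abs=1e-8)


# --------------------------------------------------------- icc/total effect

def _fit_with_components(sg2, se2):
    return DecompositionFit(
        outcome="y", predictor="x", covariates=(), alpha0=0.0, beta_w=0.1,
        beta_b=0.2, covariate_coefs={}, sigma_gamma2=sg2, sigma_eps2=se2,
        icc=np.nan, total_effect=np.nan, se={}, pvalues={}, n_pairs=10,
        n_excluded=0, loglik=0.0, method="reml", converged=True,
        boundary=False)


def test_icc_component_arithmetic():
    assert icc(_fit_with_components(0.0, 1.0)) == 0.0
    assert icc(_fit_with_components(1.0, 1.0)) == 0.5
    assert np.isnan(icc(_fit_with_components(0.0, 0.0)))


def test_icc_matches_cotwin_outcome_correlation():
    # outcome unrelated to the predictor: model ICC ~ Pearson r of co-twins
    cfg = SimulationConfig(n_families=2000, n_loci=200, beta_direct=0.0,
                           c_shared=0.6, sigma_e=0.8, seed=21)
    t = generate_cohort(cfg).table
    fit = fit_within_between(t, "outcome", "gps")
    y1 = t.loc[t["member"] == 1, "outcome"].to_numpy()
    y2 = t.loc[t["member"] == 2, "outcome"].to_numpy()
    assert fit.icc == pytest.approx(np.corrcoef(y1, y2)[0, 1], abs=0.02)


def test_total_effect_endpoints_and_midpoint():
    assert total_effect(0.2, 0.4, 0.0) == pytest.approx(0.2)
    assert total_effect(0.2, 0.4, 1.0) == pytest.approx(0.4)
    assert total_effect(0.2, 0.4, 0.5) == pytest.approx(0.3)


@given(st.floats(-2, 2), st.floats(0, 1))
def test_total_effect_identity_when_betas_equal(beta, w):
    assert total_effect(beta, beta, w) == pytest.approx(beta, abs=1e-12)


def test_total_effect_rejects_bad_icc():
    with pytest.raises(ValueError):
        total_effect(0.1, 0.2, 1.5)
    with pytest.raises(ValueError):
        total_effect(0.1, 0.2, float("nan"))


def test_fit_bounds_total_effect(small_cohort):
    fit = fit_within_between(small_cohort.table, "outcome", "gps")
    lo, hi = sorted((fit.beta_w, fit.beta_b))
    assert lo - 1e-12 <= fit.total_effect <= hi + 1e-12
    assert 0.0 <= fit.icc <= 1.0
    assert fit.sigma_gamma2 >= 0.0 and fit.sigma_eps2 > 0.0


# ------------------------------------------------------------------- errors

def test_minimum_pairs_enforced():
    df = make_pair_frame(np.random.default_rng(0).normal(size=(5, 2)),
                         np.random.default_rng(1).normal(size=(5, 2)))
    with pytest.raises(ValueError, match="pairs"):
        fit_within_between(df, "outcome", "gps")


def test_constant_outcome_rejected():
    df = make_pair_frame(np.random.default_rng(0).normal(size=(20, 2)),
                         np.zeros((20, 2)))
    with pytest.raises(ValueError, match="variance"):
        fit_within_between(df, "outcome", "gps")


def test_estimator_rejects_odd_clusters(rng):
    est = WithinBetweenRegression()
    with pytest.raises(PairStructureError):
        est.fit(rng.normal(size=(5, 1)), rng.normal(size=5),
                np.array([0, 0, 1, 1, 2]))


def test_sklearn_params_roundtrip_and_predict(rng):
    est = WithinBetweenRegression(method="ml", min_pairs=12)
    assert est.get_params()["method"] == "ml"
    est.set_params(method="reml")
    x, y = _random_pair_data(rng)
    groups = np.repeat(np.arange(x.shape[0]), 2)
    est.fit(x.reshape(-1, 1), y.ravel(), groups)
    pred = est.predict(x.reshape(-1, 1), groups)
    assert pred.shape == (2 * x.shape[0],)
    assert np.corrcoef(pred, y.ravel())[0, 1] > 0.2


def test_ml_and_reml_close_at_moderate_n(small_cohort):
    t = small_cohort.table
    f_reml = fit_within_between(t, "outcome", "gps", method="reml")
    f_ml = fit_within_between(t, "outcome", "gps", method="ml")
    assert f_ml.beta_w == pytest.approx(f_reml.beta_w, abs=1e-6)
    assert f_ml.sigma_eps2 == pytest.approx(f_reml.sigma_eps2, rel=0.05)


def test_fit_serialization_roundtrip(tmp_path, small_cohort):
    fit = fit_within_between(small_cohort.table, "outcome", "gps")
    path = tmp_path / "fit.json"
    fit.to_json(path)
    import json
    d = json.loads(path.read_text())
    assert d["beta_w"] == pytest.approx(fit.beta_w)
    assert "summary" not in d and d["n_pairs"] == fit.n_pairs
    assert "beta_within" in fit.summary()
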