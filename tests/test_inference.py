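"""Bootstrap, difference tests, attenuation and FDR."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from twinpgs.inference import (attenuation, bh_fdr, bootstrap_pairs,
                               covariate_shift_test, diff_test)
from twinpgs.simulate import SimulationConfig, generate_cohort

from conftest import make_pair_frame


@pytest.fixture(scope="module")
def cohort_table():
    cfg = SimulationConfig(n_families=800, n_loci=200, beta_nurture=0.15,
                           seed=42)
    return generate_cohort(cfg).table


def test_bootstrap_reproducible_with_seed(cohort_table):
    a = bootstrap_pairs(cohort_table, "outcome", "gps", n_boot=50, seed=9)
    b = bootstrap_pairs(cohort_table, "outcome", "gps", n_boot=50, seed=9)
    assert np.array_equal(a.replicates["base"], b.replicates["base"])


def test_bootstrap_seed_stability_of_ci(cohort_table):
    a = bootstrap_pairs(cohort_table, "outcome", "gps", n_boot=500, seed=1)
    b = bootstrap_pairs(cohort_table, "outcome", "gps", n_boot=500, seed=2)
    for coef in ("beta_w", "beta_b"):
        ca, cb = a.ci("base", coef), b.ci("base", coef)
        assert abs(ca[0] - cb[0]) < 0.02 and abs(ca[1] - cb[1]) < 0.02


def test_degenerate_outcome_equals_predictor(cohort_table):
    df = cohort_table.copy()
    df["outcome"] = df["gps"]
    boot = bootstrap_pairs(df, "outcome", "gps", n_boot=30, seed=0)
    assert np.allclose(boot.replicates["base"], 1.0)
    lo, hi = boot.ci("base", "beta_w")
    assert hi - lo == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="degenerate"):
        diff_test(boot)


def test_general_and_fast_paths_agree(cohort_table):
    # a constant covariate column exercises the general REML refit path on
    # the same resamples as the closed-form path
    df = cohort_table.assign(dummy=np.tile([0.0, 1.0],
                                           len(cohort_table) // 2))
    a = bootstrap_pairs(df, "outcome", "gps", n_boot=40, seed=3)
    b = bootstrap_pairs(df, "outcome", "gps", n_boot=40, seed=3,
                        extra_covariate_sets={"dummyless": ("dummy",)})
    assert np.array_equal(a.replicates["base"], b.replicates["base"])
    # the dummy covariate is noise: betas barely move
    assert np.allclose(b.replicates["base"], b.replicates["dummyless"],
                       atol=0.05)


def test_covariate_model_point_estimates_match_full_fit(cohort_table):
    boot = bootstrap_pairs(cohort_table, "outcome", "gps",
                           extra_covariate_sets={"ses": ("ses",)},
                           n_boot=0, seed=0)
    from twinpgs.decomposition import fit_within_between
    direct = fit_within_between(cohort_table, "outcome", "gps", ("ses",))
    assert boot.fits["ses"].beta_b == pytest.approx(direct.beta_b, abs=1e-10)


def test_diff_test_sign_and_shift_invariance(cohort_table):
    boot = bootstrap_pairs(cohort_table, "outcome", "gps", n_boot=200, seed=5)
    shifted = cohort_table.assign(outcome=cohort_table["outcome"] + 7.0)
    boot2 = bootstrap_pairs(shifted, "outcome", "gps", n_boot=200, seed=5)
    d1, d2 = diff_test(boot), diff_test(boot2)
    assert d1.z == pytest.approx(d2.z, abs=1e-10)
    assert d1.p == pytest.approx(d2.p, abs=1e-10)


def test_attenuation_arithmetic(cohort_table):
    boot = bootstrap_pairs(cohort_table, "outcome", "gps", n_boot=100, seed=1)
    boot.fits["base"].beta_w, boot.fits["base"].beta_b = 0.2, 0.4
    att = attenuation(boot)
    assert att.pct == pytest.approx(50.0)
    boot.fits["base"].beta_w = 0.4
    assert attenuation(boot).pct == pytest.approx(0.0)
    boot.fits["base"].beta_b = 0.0
    assert not attenuation(boot).defined
    assert np.isnan(attenuation(boot).pct)


def test_covariate_shift_requires_paired_models(cohort_table):
    boot = bootstrap_pairs(cohort_table, "outcome", "gps", n_boot=20, seed=0)
    with pytest.raises(ValueError, match="paired"):
        covariate_shift_test(boot, "base", "ses")


def test_covariate_shift_independent_covariate_null(cohort_table):
    rng = np.random.default_rng(0)
    df = cohort_table.assign(
        noise=np.repeat(rng.normal(size=len(cohort_table) // 2), 2))
    boot = bootstrap_pairs(df, "outcome", "gps",
                           extra_covariate_sets={"adj": ("noise",)},
                           n_boot=300, seed=8)
    res = covariate_shift_test(boot, "base", "adj")
    assert abs(res.delta) < 0.03
    assert res.p > 0.01


def test_ses_adjustment_shrinks_between_leaves_within(cohort_table):
    # nurture routed through SES: beta_b falls toward beta_w after adjustment
    boot = bootstrap_pairs(cohort_table, "outcome", "gps",
                           extra_covariate_sets={"ses": ("ses",)},
                           n_boot=300, seed=4)
    res = covariate_shift_test(boot, "base", "ses")
    assert res.delta > 0 and res.p < 0.05
    assert (abs(boot.fits["ses"].beta_w - boot.fits["base"].beta_w)
            < 0.02)


def test_resampling_unit_is_family(cohort_table):
    # co-twins must travel together: with outcome == family mean gps the
    # between slope is exactly 1 in every replicate
    df = cohort_table.copy()
    fam_mean = df.groupby("family_id")["gps"].transform("mean")
    df["outcome"] = fam_mean
    boot = bootstrap_pairs(df, "outcome", "gps", n_boot=25, seed=0)
    assert np.allclose(boot.replicates["base"][:, 1], 1.0)


# ------------------------------------------------------------------- bh_fdr

def brute_force_bh(p, alpha):
    p = np.asarray(p, float)
    m = p.size
    candidates = [pk for k, pk in enumerate(np.sort(p), start=1)
                  if pk <= k / m * alpha]
    if not candidates:
        return float("nan"), np.zeros(m, bool)
    thr = max(candidates)
    return thr, p <= thr


def test_bh_fdr_worked_example():
    res = bh_fdr([0.001, 0.012, 0.02, 0.9], alpha=0.05)
    assert res.threshold == pytest.approx(0.02)
    assert res.n_discoveries == 3


def test_bh_fdr_trivial_cases():
    assert bh_fdr([1.0, 1.0, 1.0]).n_discoveries == 0
    res = bh_fdr([0.04], alpha=0.05)
    assert res.threshold == pytest.approx(0.04) and res.n_discoveries == 1


def test_bh_fdr_input_validation():
    with pytest.raises(ValueError):
        bh_fdr([])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_fdr([0.5, -0.1])


@given(st.integers(0, 2**31 - 1), st.integers(1, 40))
def test_bh_fdr_matches_brute_force_and_statsmodels(seed, m):
    rng = np.random.default_rng(seed)
    p = np.concatenate([rng.uniform(size=m // 2),
                        rng.uniform(0, 0.05, size=m - m // 2)])
    rng.shuffle(p)
    res = bh_fdr(p, alpha=0.05)
    thr, sig = brute_force_bh(p, 0.05)
    assert np.array_equal(res.significant, sig)
    assert (np.isnan(res.threshold) and np.isnan(thr)) or \
        res.threshold == pytest.approx(thr)
    reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
    assert np.array_equal(res.significant, reject)
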