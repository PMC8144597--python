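"""Mixed-model engine: oracles, invariances, random slopes, diagnostics."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from pedsurv import (BinomialMixedModel, ModelSpec, fit_random_slope,
                     residual_diagnostics, simulate_glmm_table,
                     variance_inflation)
from pedsurv.dataset import PREDICTORS


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

def test_model_spec_from_formula():
    spec = ModelSpec.from_formula(
        "survival ~ dam_generation + offspring_f"
        " + (1|species/birth_program) + (1|species:year)"
        " + (0 + offspring_f | species)")
    assert spec.response == "survival"
    assert spec.fixed_terms == ("dam_generation", "offspring_f")
    assert spec.random_intercepts == (
        "species", "species:birth_program", "species:year")
    assert spec.random_slope == ("offspring_f", "species")


def test_model_from_spec_runs():
    df, _ = simulate_glmm_table(600, {"offspring_f": -0.4}, seed=0)
    spec = ModelSpec(fixed_terms=("offspring_f",))
    res = BinomialMixedModel.from_spec(spec, df).fit()
    assert res.converged
    assert list(res.params.index) == ["intercept", "offspring_f"]


# ---------------------------------------------------------------------------
# reduction to plain logistic regression
# ---------------------------------------------------------------------------

def test_variances_at_zero_reproduce_glm():
    """With all variance components pinned at zero the Laplace objective
    must coincide with an independent IRLS logistic regression."""
    import statsmodels.api as sm
    df, _ = simulate_glmm_table(
        1500, {"offspring_f": -0.5, "dam_age": 0.2}, intercept=0.3,
        sd_species=0.0, sd_program=0.0, sd_year=0.0, seed=2)
    res = BinomialMixedModel.from_table(df).fit(fix_sd=[0.0, 0.0, 0.0])
    X = sm.add_constant(df[list(PREDICTORS)].to_numpy())
    glm = sm.GLM(df["survival"].to_numpy(), X,
                 family=sm.families.Binomial()).fit()
    assert np.max(np.abs(res.params.to_numpy() - glm.params)) < 1e-6
    assert abs(res.llf - glm.llf) < 1e-6
    assert np.max(np.abs(res.bse.to_numpy() - glm.bse)) < 1e-6


def test_intercept_only_balanced_outcomes():
    rng = np.random.default_rng(5)
    df, _ = simulate_glmm_table(2000, {}, intercept=0.0, sd_species=0.0,
                                sd_program=0.0, sd_year=0.0, seed=5)
    df["survival"] = rng.permutation(
        np.repeat([0, 1], len(df) // 2))  # exactly balanced, no structure
    res = BinomialMixedModel.from_table(df, fixed=[]).fit()
    assert abs(res.params["intercept"]) < 3 * res.bse["intercept"]


# ---------------------------------------------------------------------------
# agreement with the reference mixed-model implementation (lme4)
# ---------------------------------------------------------------------------

def test_matches_lme4_reference(tmp_path):
    df, _ = simulate_glmm_table(
        1200, {"offspring_f": -0.4, "dam_age": 0.2}, intercept=0.3,
        n_species=5, n_programs=3, n_years=6, sd_species=0.4,
        sd_program=0.3, sd_year=0.3, seed=3)
    res = BinomialMixedModel.from_table(df).fit()
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rscript = f"""
    suppressMessages(library(lme4))
    d <- read.csv("{csv}")
    d$sp <- factor(d$species)
    d$spp <- interaction(d$species, d$birth_program)
    d$spy <- interaction(d$species, d$birth_year)
    m <- glmer(survival ~ dam_generation + sire_generation + dam_age +
               sire_age + dam_f + sire_f + offspring_f +
               (1|sp) + (1|spp) + (1|spy), data=d, family=binomial)
    cat(jsonlite::toJSON(list(beta=unname(fixef(m)),
        se=unname(sqrt(diag(vcov(m)))),
        llf=as.numeric(logLik(m))), digits=12))
    """
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr[-800:]
    ref = json.loads(out.stdout)
    assert abs(res.llf - ref["llf"][0]) < 0.05
    assert np.max(np.abs(res.params.to_numpy() - np.array(ref["beta"]))) \
        < 0.03
    assert np.max(np.abs(res.bse.to_numpy() - np.array(ref["se"]))) < 0.02


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

def test_estimates_invariant_to_row_order_and_relabeling():
    df, _ = simulate_glmm_table(800, {"offspring_f": -0.4}, seed=4)
    res1 = BinomialMixedModel.from_table(df).fit()
    shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    res2 = BinomialMixedModel.from_table(shuffled).fit()
    relabeled = df.copy()
    relabeled["species"] = relabeled["species"].map(
        lambda s: f"zz_{s[::-1]}")
    res3 = BinomialMixedModel.from_table(relabeled).fit()
    for other in (res2, res3):
        assert np.allclose(res1.params.to_numpy(), other.params.to_numpy(),
                           atol=1e-6)
        assert np.allclose(res1.vc_sd.to_numpy(), other.vc_sd.to_numpy(),
                           atol=1e-6)


# ---------------------------------------------------------------------------
# frequentist calibration
# ---------------------------------------------------------------------------

def test_wald_ci_coverage():
    """Nominal-95% CI for the offspring-inbreeding slope covers the truth
    in at least 80% of replicates (slack for the Laplace approximation)."""
    covered = 0
    n_rep = 50
    for r in range(n_rep):
        df, _ = simulate_glmm_table(
            2500, {"offspring_f": -0.3}, intercept=0.3, n_species=5,
            n_programs=2, n_years=5, seed=1000 + r)
        res = BinomialMixedModel.from_table(df).fit()
        ci = res.conf_int().loc["offspring_f"]
        covered += ci["low"] <= -0.3 <= ci["high"]
    assert covered >= 0.8 * n_rep


# ---------------------------------------------------------------------------
# random slopes
# ---------------------------------------------------------------------------

def test_random_slope_degenerate_heterogeneity():
    df, _ = simulate_glmm_table(
        6000, {"offspring_f": -0.4}, intercept=0.2, n_species=8,
        slope_sd={"offspring_f": 0.0}, seed=6)
    res = fit_random_slope("offspring_f", df)
    assert res.vc_sd["offspring_f|species"] < 0.1
    eff = res.species_effects("offspring_f")
    slope = res.params["offspring_f"]
    se = res.bse["offspring_f"]
    assert (np.abs(eff - slope) < 2 * se + 0.05).all()


def test_random_slope_recovers_heterogeneous_effects():
    df, truth = simulate_glmm_table(
        8000, {"offspring_f": -0.2}, intercept=0.3, n_species=12,
        slope_sd={"offspring_f": 0.3}, seed=7)
    res = fit_random_slope("offspring_f", df)
    eff = res.species_effects("offspring_f")
    true_eff = pd.Series(
        {s: truth["beta"]["offspring_f"] + d
         for s, d in truth["species_devs"]["offspring_f"].items()})
    strong = true_eff[true_eff.abs() > 0.3]
    match = (np.sign(eff[strong.index]) == np.sign(strong)).mean()
    assert match >= 0.8
    # BLUPs center on zero: mean species effect ~ fixed effect
    assert abs(eff.mean() - res.params["offspring_f"]) < 0.05


def test_random_slope_variance_tracks_heterogeneity():
    medians = []
    for sd in (0.0, 0.25, 0.6):
        ests = []
        for r in range(8):
            df, _ = simulate_glmm_table(
                2500, {"offspring_f": -0.2}, n_species=8,
                slope_sd={"offspring_f": sd}, seed=300 + 17 * r)
            res = fit_random_slope("offspring_f", df)
            ests.append(res.vc_sd["offspring_f|species"])
        medians.append(np.median(ests))
    assert medians[0] <= medians[1] <= medians[2]
    assert medians[0] < 0.15 and medians[2] > 0.3


# ---------------------------------------------------------------------------
# simulation from a fit
# ---------------------------------------------------------------------------

def test_simulate_shapes_and_lln():
    df, _ = simulate_glmm_table(1500, {"offspring_f": -0.4}, seed=8)
    res = BinomialMixedModel.from_table(df).fit()
    assert res.simulate(0, seed=1).shape == (0, 1500)
    sims = res.simulate(600, seed=1)
    assert sims.shape == (600, 1500)
    assert set(np.unique(sims)) <= {0.0, 1.0}
    # with the random effects integrated out, column means approximate the
    # marginal fitted probabilities
    marginal = res.simulate(4000, seed=2).mean(axis=0)
    assert np.max(np.abs(sims.mean(axis=0) - marginal)) < 0.08


def test_simulate_saturated_probabilities():
    df, _ = simulate_glmm_table(300, {}, seed=9)
    res = BinomialMixedModel.from_table(df, fixed=[]).fit(
        fix_sd=[0.0, 0.0, 0.0])
    res.params[:] = [40.0]  # push every fitted probability to 1
    res.vc_sd[:] = 0.0
    assert (res.simulate(20, seed=3) == 1.0).all()


def test_simulate_deterministic_under_seed():
    df, _ = simulate_glmm_table(400, {"offspring_f": -0.4}, seed=10)
    res = BinomialMixedModel.from_table(df).fit()
    assert np.array_equal(res.simulate(5, seed=11), res.simulate(5, seed=11))


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_model():
    df, _ = simulate_glmm_table(2500, {"offspring_f": -0.3}, intercept=0.3,
                                seed=12)
    return df, BinomialMixedModel.from_table(df).fit()


def test_diagnostics_calibrated_under_correct_model(fitted_model):
    """On data simulated from the fitted model itself, the KS uniformity
    test rejects at about its nominal rate."""
    df, res = fitted_model
    ks_rej = disp_rej = 0
    n_runs = 40
    for r in range(n_runs):
        ysim = res.simulate(1, seed=500 + r, conditional=True)[0]
        d = residual_diagnostics(res, n_sims=100, seed=r, observed=ysim)
        ks_rej += d.ks_uniformity_p < 0.05
        disp_rej += d.dispersion_p < 0.05
    assert ks_rej <= 0.10 * n_runs + 2
    assert disp_rej <= 0.10 * n_runs + 2


def test_diagnostics_detect_zero_inflation(fitted_model):
    df, res = fitted_model
    rng = np.random.default_rng(13)
    y = df["survival"].to_numpy(dtype=float).copy()
    y[rng.random(len(y)) < 0.2] = 0.0  # 20% forced zeros
    d = residual_diagnostics(res, n_sims=250, seed=14, observed=y)
    assert d.zero_inflation_ratio > 1.0
    assert d.zero_inflation_p < 0.05


def test_dispersion_near_one_for_bernoulli(fitted_model):
    # unit-level Bernoulli data cannot be overdispersed; the check should
    # sit inside its simulation envelope
    df, res = fitted_model
    d = residual_diagnostics(res, n_sims=250, seed=15)
    assert 0.8 < d.dispersion_ratio < 1.2
    assert d.dispersion_p > 0.05
    assert d.outlier_fraction == 0.0 and d.outlier_p > 0.5
    assert 0.0 <= d.ks_uniformity_p <= 1.0


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def _orthonormal_pair(n=64, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a -= a.mean()
    a /= np.linalg.norm(a)
    b -= b.mean()
    b -= (b @ a) * a
    b /= np.linalg.norm(b)
    return a, b


def test_vif_orthogonal_predictors():
    u, v = _orthonormal_pair()
    data = pd.DataFrame({"x1": u, "x2": v})
    vif = variance_inflation(data, ["x1", "x2"])
    assert np.allclose(vif.to_numpy(), 1.0, atol=1e-10)


def test_vif_correlation_point_six():
    u, v = _orthonormal_pair(seed=1)
    data = pd.DataFrame({"x1": u, "x2": 0.6 * u + 0.8 * v})
    vif = variance_inflation(data, ["x1", "x2"])
    assert vif["x1"] == pytest.approx(1.0 / (1.0 - 0.36), abs=1e-9)
    assert vif["x2"] == pytest.approx(1.5625, abs=1e-9)


def test_vif_duplicated_column_infinite():
    u, v = _orthonormal_pair(seed=2)
    data = pd.DataFrame({"x1": u, "x2": u.copy(), "x3": v})
    with pytest.warns(UserWarning, match="high collinearity"):
        vif = variance_inflation(data, ["x1", "x2", "x3"])
    assert np.isinf(vif["x1"]) and np.isinf(vif["x2"])
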