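"""The Laplace binomial mixed logit: GLM reduction, invariants, and an
independent cross-check against lme4's glmer."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from riskscape.design import ModelSpec, build_design
from riskscape.glmm import BinomialMixedLogit, FitResult, fit_glmm, wald_table


def _logistic_data(n=400, p=3, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p)])
    if beta is None:
        beta = rng.uniform(-1, 1, p + 1)
    prob = 1 / (1 + np.exp(-(X @ beta)))
    y = rng.binomial(1, prob)
    return X, y


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_glm_reduction_matches_irls_oracle(seed):
    """With no random structure the fit equals statsmodels' IRLS logistic."""
    import statsmodels.api as sm

    X, y = _logistic_data(seed=seed)
    mine = BinomialMixedLogit(random="none").fit(X, y)
    oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(mine.result_.estimate, oracle.params, atol=1e-6)
    assert mine.result_.loglik == pytest.approx(oracle.llf, abs=1e-6)
    np.testing.assert_allclose(mine.result_.se, oracle.bse, atol=1e-5)
    # AIC parameter count is the number of fixed effects
    assert mine.result_.aic == pytest.approx(-2 * oracle.llf + 2 * X.shape[1], abs=1e-5)


def test_aic_identity_holds():
    X, y = _logistic_data(seed=3)
    site = np.arange(len(y)) % 25
    m = BinomialMixedLogit(random="site").fit(X, y, site=site)
    r = m.result_
    assert r.aic == pytest.approx(-2 * r.loglik + 2 * r.n_params, abs=1e-10)
    assert r.n_params == X.shape[1] + 1


def test_wald_identities_and_degenerate_se():
    X, y = _logistic_data(seed=4)
    m = BinomialMixedLogit(random="none").fit(X, y)
    tab = wald_table(m.result_)
    np.testing.assert_allclose(tab["z"], m.result_.estimate / m.result_.se)
    # z = 0 gives p = 1 exactly
    r = m.result_
    fake = FitResult(
        terms=["a"], estimate=np.array([0.0]), se=np.array([1.3]),
        vcov=np.eye(1), sigma_site=None, sigma_box=None, loglik=0.0, aic=0.0,
        n_obs=1, n_params=1, converged=True, fitted=np.array([0.5]),
    )
    t = wald_table(fake)
    assert t["z"].item() == 0.0
    assert t["p"].item() == 1.0
    broken = FitResult(
        terms=["a"], estimate=np.array([1.0]), se=np.array([0.0]),
        vcov=np.zeros((1, 1)), sigma_site=None, sigma_box=None, loglik=0.0,
        aic=0.0, n_obs=1, n_params=1, converged=True, fitted=np.array([0.5]),
    )
    with pytest.raises(ValueError):
        wald_table(broken)


def test_wald_invariant_to_covariate_rescaling():
    X, y = _logistic_data(seed=5)
    m1 = BinomialMixedLogit(random="none").fit(X, y)
    X2 = X.copy()
    X2[:, 1] *= 37.5
    m2 = BinomialMixedLogit(random="none").fit(X2, y)
    np.testing.assert_allclose(m1.result_.z, m2.result_.z, atol=1e-6)
    np.testing.assert_allclose(m1.result_.p, m2.result_.p, atol=1e-8)


def test_destandardisation_round_trip():
    """Slopes fitted on standardised covariates map exactly back to raw-scale
    slopes (GLM case)."""
    rng = np.random.default_rng(6)
    n = 300
    raw = rng.uniform(5, 20, n)
    X_raw = np.column_stack([np.ones(n), raw])
    y = rng.binomial(1, 1 / (1 + np.exp(-(0.3 * (raw - 12)))))
    mean, sd = raw.mean(), raw.std(ddof=1)
    X_std = np.column_stack([np.ones(n), (raw - mean) / sd])
    fit_raw = BinomialMixedLogit(random="none").fit(X_raw, y).result_
    fit_std = BinomialMixedLogit(random="none").fit(X_std, y).result_
    assert fit_std.estimate[1] / sd == pytest.approx(fit_raw.estimate[1], abs=1e-6)
    assert fit_std.estimate[0] - fit_std.estimate[1] * mean / sd == pytest.approx(
        fit_raw.estimate[0], abs=1e-6
    )
    assert fit_std.loglik == pytest.approx(fit_raw.loglik, abs=1e-8)


def _mixed_data(S=60, B_per=2, Y=6, seed=7, sigma_site=1.0, sigma_box=0.5):
    rng = np.random.default_rng(seed)
    n = S * B_per * Y
    site = np.repeat(np.arange(S), B_per * Y)
    box = np.repeat(np.arange(S * B_per), Y)
    x = rng.normal(size=n)
    eta = -0.4 + 0.9 * x + rng.normal(0, sigma_site, S)[site]
    if sigma_box > 0:
        eta = eta + rng.normal(0, sigma_box, S * B_per)[box]
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    return pd.DataFrame({"y": y, "x": x, "site": site, "box": box})


def test_zero_variance_truth_close_to_glm():
    """When the random-effect truth is 0, fixed effects match plain logistic."""
    d = _mixed_data(S=80, Y=4, seed=8, sigma_site=0.0, sigma_box=0.0)
    X = np.column_stack([np.ones(len(d)), d.x])
    glm = BinomialMixedLogit(random="none").fit(X, d.y).result_
    mixed = BinomialMixedLogit(random="site_box").fit(
        X, d.y, site=d.site, box=d.box
    ).result_
    np.testing.assert_allclose(mixed.estimate, glm.estimate, atol=1e-2)
    assert mixed.sigma_site < 0.3
    assert mixed.sigma_box < 0.3


def test_nesting_violation_detected():
    d = _mixed_data(S=10, Y=4, seed=9)
    box = d.box.copy()
    box.iloc[0] = 19  # box 19 belongs to another site
    X = np.column_stack([np.ones(len(d)), d.x])
    with pytest.raises(ValueError, match="nested"):
        BinomialMixedLogit(random="site_box").fit(X, d.y, site=d.site, box=box)


def test_separation_warns():
    x = np.concatenate([-np.ones(12), np.ones(12)])
    y = (x > 0).astype(float)
    X = np.column_stack([np.ones(24), x])
    with pytest.warns(RuntimeWarning, match="separation"):
        BinomialMixedLogit(random="none", max_inner=400).fit(X, y)


def test_matches_glmer_oracle():
    """Independent cross-check: lme4's glmer (Laplace) on the same data."""
    d = _mixed_data(S=80, B_per=2, Y=6, seed=10)
    X = np.column_stack([np.ones(len(d)), d.x])
    mine = BinomialMixedLogit(random="site_box").fit(
        X, d.y, site=d.site, box=d.box, feature_names=["Intercept", "x"]
    ).result_
    csv = "/tmp/riskscape_glmer_check.csv"
    d.to_csv(csv, index=False)
    rscript = (
        "suppressMessages(library(lme4));"
        f"d <- read.csv('{csv}');"
        "m <- glmer(y ~ x + (1|site) + (1|box), data=d, family=binomial,"
        " control=glmerControl(optimizer='bobyqa'));"
        "cat(fixef(m), as.numeric(logLik(m)),"
        " attr(VarCorr(m)$site,'stddev'), attr(VarCorr(m)$box,'stddev'), sep=',')"
    )
    try:
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
    except (FileNotFoundError, subprocess.TimeoutExpired):
        pytest.skip("Rscript unavailable")
    if out.returncode != 0:
        pytest.skip(f"glmer oracle failed: {out.stderr[-200:]}")
    b0, b1, ll, ss, sb = map(float, out.stdout.strip().split(","))
    assert mine.estimate[0] == pytest.approx(b0, abs=5e-3)
    assert mine.estimate[1] == pytest.approx(b1, abs=5e-3)
    assert mine.loglik == pytest.approx(ll, abs=5e-3)
    assert mine.sigma_site == pytest.approx(ss, abs=2e-2)
    assert mine.sigma_box == pytest.approx(sb, abs=5e-2)


def test_fit_glmm_wrapper_uses_spec_random_structure(small_red_dataset, table_builder):
    table = table_builder(small_red_dataset)
    spec = ModelSpec(mandatory=["year", "time_period"], habitat=["Field"],
                     risk=["goshawk"], random="site")
    fit = fit_glmm(build_design(table, spec))
    assert fit.sigma_site is not None
    assert fit.sigma_box is None
    assert fit.converged
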