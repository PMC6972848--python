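import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parklens import models as md
from parklens.exceptions import ValidationError
from parklens.users import CompositionTable


def _nb_sim(rng, n, beta, theta, offsets=None):
    x = rng.standard_normal(n)
    off = offsets if offsets is not None else rng.integers(10, 60, n).astype(float)
    mu = off * np.exp(beta[0] + beta[1] * x)
    y = rng.poisson(rng.gamma(theta, mu / theta))
    return y, off, pd.DataFrame({"x": x})


# --- scaling and VIF -----------------------------------------------------

def test_scale_regressors_example_and_idempotence():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    Xs = md.scale_regressors(X)
    assert np.allclose(Xs["a"], [-1, 0, 1])  # sample sd (ddof=1)
    assert np.allclose(md.scale_regressors(Xs)["a"], Xs["a"], atol=1e-12)
    with pytest.raises(ValidationError, match="constant"):
        md.scale_regressors(pd.DataFrame({"c": [1.0, 1.0, 1.0]}))


def test_scaling_preserves_maximized_likelihood(rng):
    y, off, X = _nb_sim(rng, 800, (-2.0, 0.4), 2.0)
    X["x"] = X["x"] * 3.0 + 5.0
    ll_raw = md.fit_nb_offset(y, off, X).loglik
    ll_scaled = md.fit_nb_offset(y, off, md.scale_regressors(X)).loglik
    assert ll_raw == pytest.approx(ll_scaled, abs=1e-4)


def test_vif_orthogonal_columns(rng):
    X = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("abc"))
    # orthogonalize explicitly
    Q, _ = np.linalg.qr(X - X.mean())
    v = md.vif(pd.DataFrame(Q, columns=list("abc")))
    assert np.allclose(v, 1.0, atol=1e-9)


def test_vif_controlled_r_squared(rng):
    x1 = rng.standard_normal(1000)
    x1 -= x1.mean()
    e = rng.standard_normal(1000)
    e -= e.mean()
    e -= x1 * (e @ x1) / (x1 @ x1)  # make e empirically orthogonal
    # construct x2 with sample R^2 exactly 0.75 on x1
    x2 = x1 / np.linalg.norm(x1) * np.sqrt(0.75) \
        + e / np.linalg.norm(e) * np.sqrt(0.25)
    v = md.vif(pd.DataFrame({"x1": x1, "x2": x2}))
    assert v["x2"] == pytest.approx(4.0, rel=1e-6)


def test_vif_duplicate_column_is_infinite(rng):
    x = rng.standard_normal(100)
    with pytest.warns(UserWarning, match="collinear"):
        v = md.vif(pd.DataFrame({"a": x, "b": x}))
    assert np.isinf(v["a"]) and np.isinf(v["b"])


# --- negative binomial with offset ---------------------------------------

def test_nb_loglik_matches_brute_force_logpmf(rng):
    y, off, X = _nb_sim(rng, 10, (-2.0, 0.5), 2.0)
    mu = off * np.exp(-1.9 + 0.4 * X["x"].to_numpy())
    theta = 1.7
    ref = stats.nbinom.logpmf(y, theta, theta / (theta + mu)).sum()
    assert md.nb2_loglik(y, mu, theta) == pytest.approx(ref, abs=1e-10)


def test_nb_fit_recovers_parameters(rng):
    y, off, X = _nb_sim(rng, 3000, (-3.0, 0.5), 2.0)
    fit = md.fit_nb_offset(y, off, X)
    assert abs(fit.beta["intercept"] + 3.0) < 3 * fit.se["intercept"]
    assert abs(fit.beta["x"] - 0.5) < 3 * fit.se["x"]
    assert fit.theta > 0
    assert fit.aic == pytest.approx(2 * 3 - 2 * fit.loglik, abs=1e-9)


def test_nb_large_fixed_theta_matches_poisson(rng):
    x = rng.standard_normal(2000)
    off = rng.integers(10, 40, 2000).astype(float)
    mu = off * np.exp(-2.0 + 0.3 * x)
    y = rng.poisson(mu)
    X = pd.DataFrame({"x": x})
    fit = md.fit_nb_offset(y, off, X, theta=1e8)
    import statsmodels.api as sm
    pois = sm.GLM(y, sm.add_constant(X), family=sm.families.Poisson(),
                  offset=np.log(off)).fit()
    assert np.allclose(fit.beta.to_numpy(), pois.params.to_numpy(), atol=1e-4)


def test_nb_fit_rejects_bad_inputs(rng):
    X = pd.DataFrame({"x": [0.1, 0.2, 0.3]})
    with pytest.raises(ValidationError):
        md.fit_nb_offset([0, 0, 0], [10, 10, 10], X)
    with pytest.raises(ValidationError):
        md.fit_nb_offset([1, 2, 1], [0, 10, 10], X)


# --- stepwise ------------------------------------------------------------

def _ols_like_fit(y, X):
    import statsmodels.api as sm
    res = sm.OLS(y, sm.add_constant(X) if len(X.columns) else
                 np.ones((len(y), 1))).fit()
    params = pd.Series(np.atleast_1d(res.params))
    if len(X.columns):
        params.index = ["intercept"] + list(X.columns)
    else:
        params.index = ["intercept"]
    class F:
        aic = res.aic
        pvalues = res.pvalues
        beta = params
    return F()


def test_stepwise_removes_noise_keeps_signal(rng):
    n = 2000
    X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["s1", "s2", "noise"])
    y = 1.0 + 0.5 * X["s1"] - 0.4 * X["s2"] + rng.standard_normal(n)
    trace = md.stepwise_aic(lambda names: _ols_like_fit(y, X[names]),
                            ["s1", "s2", "noise"])
    assert "noise" not in trace.kept
    assert set(trace.kept) >= {"s1", "s2"}
    aics = [a for _, a in trace.steps]
    assert all(b < a for a, b in zip(aics, aics[1:]))  # AIC strictly falls


def test_stepwise_all_predictive_is_single_step(rng):
    n = 500
    X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
    y = 2 * X["a"] + 2 * X["b"] + 0.1 * rng.standard_normal(n)
    trace = md.stepwise_aic(lambda names: _ols_like_fit(y, X[names]), ["a", "b"])
    assert len(trace.steps) == 1 and trace.kept == ["a", "b"]


def test_stepwise_empty_candidates(rng):
    y = rng.standard_normal(50)
    X = pd.DataFrame(index=range(50))
    trace = md.stepwise_aic(lambda names: _ols_like_fit(y, X[names]), [])
    assert len(trace.steps) == 1


# --- Dirichlet -----------------------------------------------------------

def test_dirichlet_compress_examples():
    Y = CompositionTable(list(range(99)), ["a", "b", "c"],
                         np.vstack([[1.0, 0.0, 0.0]] + [[1 / 3] * 3] * 98))
    Yc = md.dirichlet_compress(Y)
    expect = np.array([98 + 1 / 3, 1 / 3, 1 / 3]) / 99
    assert np.allclose(Yc.proportions[0], expect, atol=1e-12)
    assert np.allclose(Yc.proportions[1], 1 / 3, atol=1e-12)  # fixed point
    # limit: compression vanishes as n grows
    big = CompositionTable(list(range(5000)), ["a", "b"],
                           np.tile([0.9, 0.1], (5000, 1)))
    assert np.allclose(md.dirichlet_compress(big).proportions[0],
                       [0.9, 0.1], atol=1e-3)


def test_dirichlet_loglik_matches_scipy_rowwise(rng):
    alpha = rng.uniform(0.5, 4.0, size=(8, 3))
    Y = np.vstack([rng.dirichlet(a) for a in alpha])
    ref = sum(stats.dirichlet.logpdf(y, a) for y, a in zip(Y, alpha))
    assert md.dirichlet_loglik(alpha, Y) == pytest.approx(ref, abs=1e-10)


def test_dirichlet_intercept_only_recovery(rng):
    Y = rng.dirichlet([2.0, 3.0, 5.0], size=2000)
    ct = md.dirichlet_compress(
        CompositionTable(list(range(2000)), list("abc"), Y))
    fit = md.fit_dirichlet(ct, pd.DataFrame(index=range(2000)))
    mean = np.exp(fit.beta.loc["intercept"].to_numpy())
    mean /= mean.sum()
    assert np.abs(mean - np.array([0.2, 0.3, 0.5])).max() < 0.02


def test_dirichlet_regression_recovers_slope(rng):
    n = 1500
    x = rng.standard_normal(n)
    beta = np.array([[np.log(2), np.log(2), np.log(2)],
                     [0.5, 0.0, -0.5]])
    alpha = np.exp(np.column_stack([np.ones(n), x]) @ beta)
    Y = np.vstack([rng.dirichlet(a) for a in alpha])
    ct = md.dirichlet_compress(
        CompositionTable(list(range(n)), list("abc"), Y))
    fit = md.fit_dirichlet(ct, pd.DataFrame({"x": x}))
    est = fit.beta.loc["x"].to_numpy()
    se = fit.se.loc["x"].to_numpy()
    assert np.all(np.abs(est - beta[1]) < 3.5 * se)


def test_dirichlet_two_parts_reduce_to_beta(rng):
    n = 300
    Y = rng.beta(2.0, 3.0, size=n)
    Ymat = np.column_stack([Y, 1 - Y])
    ct = CompositionTable(list(range(n)), ["a", "b"], Ymat)
    fit = md.fit_dirichlet(ct, pd.DataFrame(index=range(n)))
    a, b = np.exp(fit.beta.loc["intercept"].to_numpy())
    ref = stats.beta.logpdf(Y, a, b).sum()
    assert fit.loglik == pytest.approx(ref, abs=1e-6)


def test_dirichlet_rejects_boundary_compositions():
    ct = CompositionTable([0, 1], ["a", "b"], np.array([[1.0, 0.0], [0.5, 0.5]]))
    with pytest.raises(ValidationError, match="dirichlet_compress"):
        md.fit_dirichlet(ct, pd.DataFrame(index=range(2)))
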