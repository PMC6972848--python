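"""Regression models of park photography behaviour.

Two families model user-level behaviour:

* counts of park photographs — negative binomial (NB2, Var = mu +
  mu^2/theta) with a log link and the log of the user's total upload
  count as an offset, so the model describes the *rate* of park
  photography per upload;
* the composition of park photographs over categories — Dirichlet
  regression in the 'common' parameterisation, where every component's
  concentration is log-linear in the regressors:
  log alpha_ic = x_i' beta_c.

Regressors (residential status and the four user-axis scores) are
standardized before fitting; backward stepwise selection by AIC and VIF
multicollinearity diagnostics round out the workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .exceptions import FitError, ValidationError
from .users import CompositionTable

__all__ = ["NBFit", "DirichletFit", "StepwiseTrace", "scale_regressors",
           "fit_nb_offset", "stepwise_aic", "vif", "dirichlet_compress",
           "fit_dirichlet", "nb2_loglik", "dirichlet_loglik"]


@dataclass
class NBFit:
    beta: pd.Series        # intercept + one coefficient per regressor
    theta: float           # NB2 dispersion (> 0); Var = mu + mu^2/theta
    se: pd.Series
    loglik: float
    aic: float
    n: int
    converged: bool = True

    @property
    def pvalues(self) -> pd.Series:
        from scipy.stats import norm
        z = self.beta / self.se
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.beta.index)


@dataclass
class DirichletFit:
    beta: pd.DataFrame     # (intercept + regressors) x components, log-alpha scale
    se: pd.DataFrame
    loglik: float
    aic: float
    n: int
    components: list

    def alphas(self, X: pd.DataFrame | None = None,
               Xmat: np.ndarray | None = None) -> np.ndarray:
        if Xmat is None:
            Xmat = _design(X, list(self.beta.index[1:]))
        return np.exp(Xmat @ self.beta.to_numpy())

    def fitted_means(self, X: pd.DataFrame) -> np.ndarray:
        a = self.alphas(X)
        return a / a.sum(axis=1, keepdims=True)


@dataclass
class StepwiseTrace:
    steps: list            # (dropped regressor or None, aic after the step)
    final: object          # the final fit

    @property
    def kept(self) -> list:
        return [name for name in self.final.beta.index if name != "intercept"]


def scale_regressors(X: pd.DataFrame) -> pd.DataFrame:
    """Standardize every column to mean 0, sd 1 (sample sd, ddof=1).

    The binary status column is standardized identically to the
    continuous axes, matching a workflow that scales all regressors;
    coefficients are then per-SD effects.
    """
    sd = X.std(ddof=1)
    bad = sd.index[~(sd > 0)]
    if len(bad):
        raise ValidationError(f"constant column(s) cannot be scaled: {list(bad)}")
    return (X - X.mean()) / sd


def _design(X: pd.DataFrame, names: list[str] | None = None) -> np.ndarray:
    if names is not None:
        X = X[names]
    if X.isna().any().any():
        raise ValidationError("design matrix contains missing values")
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def nb2_loglik(counts: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood (direct summation form, used as the reference)."""
    y = np.asarray(counts, dtype=float)
    return float(np.sum(
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))))


def fit_nb_offset(counts, offsets, X: pd.DataFrame,
                  theta: float | None = None) -> NBFit:
    """NB2 regression of counts with log(offset) exposure.

    log mu_i = log(offset_i) + x_i' beta;  Var = mu + mu^2 / theta.
    With ``theta=None`` (default), (beta, theta) are estimated jointly
    by maximum likelihood; passing a fixed ``theta`` fits beta alone
    via a GLM with known dispersion (theta -> inf approaches Poisson).
    """
    y = np.asarray(counts, dtype=float)
    off = np.asarray(offsets, dtype=float)
    if np.any(y < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(off < 1):
        raise ValidationError("offsets (total uploads) must be >= 1")
    if not np.any(y > 0):
        raise ValidationError("all counts are zero; nothing to model")
    names = ["intercept"] + list(X.columns)
    exog = _design(X)
    log_off = np.log(off)
    if theta is not None:
        fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
        res = sm.GLM(y, exog, family=fam, offset=log_off).fit()
        beta = pd.Series(res.params, index=names)
        mu = off * np.exp(exog @ res.params)
        ll = nb2_loglik(y, mu, theta)
        aic = 2 * len(beta) - 2 * ll
        return NBFit(beta, float(theta), pd.Series(res.bse, index=names),
                     ll, aic, len(y))
    start = sm.Poisson(y, exog, offset=log_off).fit(disp=0).params
    model = sm.NegativeBinomial(y, exog, offset=log_off,
                                loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=np.append(start, 0.5),
                        method="bfgs", maxiter=500, disp=0, gtol=1e-8)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(start_params=res.params, method="nm",
                            maxiter=5000, disp=0)
    if not res.mle_retvals.get("converged", False):
        raise FitError("negative binomial fit did not converge",
                       trace=res.mle_retvals)
    alpha = float(res.params[-1])
    if alpha <= 0:  # boundary: effectively Poisson
        alpha = 1e-8
    beta = pd.Series(res.params[:-1], index=names)
    se = pd.Series(res.bse[:-1], index=names)
    ll = float(res.llf)
    aic = 2 * (len(beta) + 1) - 2 * ll  # +1 for the estimated theta
    return NBFit(beta, 1.0 / alpha, se, ll, aic, len(y))


def stepwise_aic(fit_fn, regressors: list[str],
                 forced: list[str] | None = None,
                 p_threshold: float | None = 0.05) -> StepwiseTrace:
    """Backward elimination guided by p-values and AIC.

    ``fit_fn(names)`` must fit the model with that regressor subset and
    return an object exposing ``aic`` and ``pvalues``.  Each step first
    drops the least significant candidate when its p-value exceeds
    ``p_threshold``; otherwise it drops the candidate whose removal
    lowers AIC most (AIC ties: the larger p-value first).  Selection
    stops when every candidate is significant and no removal lowers
    AIC.  With ``p_threshold=None`` the rule is pure backward-AIC, in
    which case the recorded AIC trace is non-increasing.
    """
    forced = list(forced or [])
    current = list(regressors)
    fit = fit_fn(forced + current)
    steps = [(None, fit.aic)]
    while current:
        pv = fit.pvalues
        dropped, new_fit = None, None
        if p_threshold is not None:
            worst = max(current, key=lambda r: pv.get(r, 0.0))
            if pv.get(worst, 0.0) > p_threshold:
                dropped = worst
                new_fit = fit_fn(forced + [r for r in current if r != worst])
        if dropped is None:
            # candidates ordered by descending p-value so AIC ties drop
            # the least significant regressor first
            order = sorted(current, key=lambda r: -pv.get(r, 0.0))
            for name in order:
                trial = fit_fn(forced + [r for r in current if r != name])
                if trial.aic < fit.aic - 1e-12 and \
                        (new_fit is None or trial.aic < new_fit.aic - 1e-12):
                    dropped, new_fit = name, trial
        if dropped is None:
            break
        current.remove(dropped)
        fit = new_fit
        steps.append((dropped, fit.aic))
    return StepwiseTrace(steps, fit)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: 1 / (1 - R^2_j) of each regressor on
    the rest (with intercept).  Perfect collinearity reports inf."""
    if X.shape[1] < 2:
        raise ValidationError("VIF needs at least 2 regressors")
    if len(X) <= X.shape[1]:
        raise ValidationError("VIF needs n > number of regressors")
    out = {}
    cols = list(X.columns)
    A = X.to_numpy(dtype=float)
    for j, name in enumerate(cols):
        yj = A[:, j]
        others = np.column_stack(
            [np.ones(len(A)), np.delete(A, j, axis=1)])
        resid = yj - others @ np.linalg.lstsq(others, yj, rcond=None)[0]
        sst = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"regressor {name!r} is perfectly collinear "
                          "with the others; VIF is infinite", stacklevel=2)
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def dirichlet_compress(Y: CompositionTable) -> CompositionTable:
    """Shrink compositions away from the simplex boundary.

    y* = (y * (n - 1) + 1/C) / n entrywise, then re-closed; the standard
    transform for extreme values ahead of Dirichlet likelihoods.  The
    uniform composition is a fixed point, and y* -> y as n grows.
    """
    y = np.asarray(Y.proportions, dtype=float)
    n, C = y.shape
    ystar = (y * (n - 1) + 1.0 / C) / n
    ystar = ystar / ystar.sum(axis=1, keepdims=True)
    return CompositionTable(list(Y.user_ids), list(Y.categories), ystar)


def dirichlet_loglik(alpha: np.ndarray, Y: np.ndarray) -> float:
    """Dirichlet log-density summed over rows (reference form)."""
    return float(np.sum(
        gammaln(alpha.sum(axis=1)) - gammaln(alpha).sum(axis=1)
        + ((alpha - 1.0) * np.log(Y)).sum(axis=1)))


def fit_dirichlet(Y: CompositionTable, X: pd.DataFrame,
                  regressors: list[str] | None = None) -> DirichletFit:
    """Dirichlet regression, 'common' parameterisation.

    log alpha_ic = x_i' beta_c for every component c; maximum likelihood
    by quasi-Newton with analytic gradient (tolerance 1e-8); standard
    errors from the inverse observed information.
    """
    yv = np.asarray(Y.proportions, dtype=float)
    if np.any(yv <= 0) or np.any(yv >= 1):
        raise ValidationError(
            "composition must be strictly interior to the simplex; "
            "apply dirichlet_compress first")
    if regressors is None:
        regressors = list(X.columns)
    Xmat = _design(X, regressors)
    if Xmat.shape[0] != yv.shape[0]:
        raise ValidationError("X and Y row counts differ")
    n, C = yv.shape
    p = Xmat.shape[1]
    logy = np.log(yv)

    def unpack(vec):
        return vec.reshape(p, C)

    def negll_grad(vec):
        beta = unpack(vec)
        eta = Xmat @ beta
        eta = np.clip(eta, -30, 30)
        alpha = np.exp(eta)
        a0 = alpha.sum(axis=1)
        ll = np.sum(gammaln(a0) - gammaln(alpha).sum(axis=1)
                    + ((alpha - 1.0) * logy).sum(axis=1))
        dl_dalpha = digamma(a0)[:, None] - digamma(alpha) + logy
        grad = Xmat.T @ (alpha * dl_dalpha)  # (p, C)
        return -ll, -grad.ravel()

    # moment-matched intercept start: alpha ~ C * mean composition
    beta0 = np.zeros((p, C))
    beta0[0] = np.log(np.maximum(yv.mean(axis=0) * C, 1e-3))
    res = minimize(negll_grad, beta0.ravel(), jac=True, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 2000})
    if not res.success and np.linalg.norm(res.jac) > 1e-4 * max(1.0, abs(res.fun)):
        raise FitError(f"Dirichlet fit did not converge: {res.message}",
                       trace=res)
    beta = unpack(res.x)
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(res.x, lambda v: negll_grad(v)[0])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(p, C)
    except np.linalg.LinAlgError:
        se = np.full((p, C), np.nan)
    names = ["intercept"] + list(regressors)
    comp_names = list(Y.categories)
    ll = -float(res.fun)
    return DirichletFit(
        beta=pd.DataFrame(beta, index=names, columns=comp_names),
        se=pd.DataFrame(se, index=names, columns=comp_names),
        loglik=ll, aic=2 * p * C - 2 * ll, n=n, components=comp_names)
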