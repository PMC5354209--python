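"""Candidate cost estimators and retransformation machinery.

Two estimator classes model positive annual costs Y given age, sex and
morbidity:

* :class:`GLMCostModel` — generalized linear model with a natural-log link,
  ``Y_i = exp(alpha + X_i beta + eps_i)``, fitted by iteratively reweighted
  least squares under one of four variance functions (Gaussian ``V(mu)=1``,
  Poisson ``V(mu)=mu``, gamma ``V(mu)=mu^2``, inverse Gaussian
  ``V(mu)=mu^3``).
* :class:`LogOLSCostModel` — ordinary least squares on log costs,
  ``log Y_i = alpha + X_i beta + eps_i``; EUR-scale predictions require a
  retransformation factor (Duan smearing, or a normal-theory heteroscedastic
  factor driven by a secondary variance model).

Both follow the scikit-learn estimator contract (``fit``/``predict``,
``get_params``, fitted attributes with a trailing underscore) and compose
with sklearn pipelines.  Module-level functions mirror the estimators for a
functional style over :class:`~costlines.design.DesignMatrix` objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .design import DesignMatrix
from .exceptions import ConvergenceError

GLM_FAMILIES = ("gaussian", "poisson", "gamma", "inverse_gaussian")

#: Variance-function exponent lambda in V(mu) = mu^lambda, per family.
FAMILY_POWER = {"gaussian": 0, "poisson": 1, "gamma": 2, "inverse_gaussian": 3}


@dataclass
class VarianceModel:
    """Secondary variance model: log squared residuals regressed on the design.

    Per-row variance is ``v(x) = calibration * exp(x gamma)``, with the
    method-of-moments calibration constant chosen so the mean fitted variance
    equals the mean squared residual.
    """

    gamma: np.ndarray
    calibration: float
    resid_var: float
    column_names: tuple[str, ...] = ()
    n_zero_replaced: int = 0

    def predict_variance(self, exog: np.ndarray) -> np.ndarray:
        exog = np.asarray(exog, dtype=float)
        return self.calibration * np.exp(exog @ self.gamma)


@dataclass
class FittedModel:
    """A fitted cost model in the shape the selection pipeline consumes."""

    branch: str                      # "GLM" or "LOG_OLS"
    family: str | None               # variance family; None for LOG_OLS
    alpha: float                     # intercept (log scale)
    beta: np.ndarray                 # non-intercept coefficients (log scale)
    vcov_model: np.ndarray           # model-based covariance (incl. intercept)
    vcov_robust: np.ndarray          # Huber-White sandwich covariance
    eta: np.ndarray                  # linear predictor per row
    mu: np.ndarray | None            # EUR-scale fitted mean per row
    resid_raw: np.ndarray | None     # y - mu (None until mu available)
    resid_log: np.ndarray            # log y - eta
    n: int
    dispersion: float = 1.0
    column_names: tuple[str, ...] = ()

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.alpha], self.beta])

    def se(self, robust: bool = False) -> np.ndarray:
        v = self.vcov_robust if robust else self.vcov_model
        return np.sqrt(np.diag(v))


def _check_Xy(X, y, require_positive: bool = True):
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        names = tuple(f"x{i}" for i in range(Xa.shape[1]))
    y = np.asarray(y, dtype=float).ravel()
    if Xa.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    if not np.all(np.isfinite(Xa)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")
    if require_positive and np.any(y <= 0):
        raise ValueError("all costs must be strictly positive")
    return Xa, y, names


def _quasi_deviance(y: np.ndarray, mu: np.ndarray, power: int) -> float:
    """Quasi-deviance for the power variance family V(mu) = mu^power."""
    if power == 0:
        return float(np.sum((y - mu) ** 2))
    if power == 1:
        return float(2.0 * np.sum(y * np.log(y / mu) - (y - mu)))
    if power == 2:
        return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))
    return float(np.sum((y - mu) ** 2 / (mu**2 * y)))


_ETA_CLIP = 250.0  # |linear predictor| bound during IRLS (exp stays finite)


def irls_log_link(exog: np.ndarray, y: np.ndarray, family: str,
                  start: np.ndarray | None = None, max_iter: int = 100,
                  tol: float = 1e-8) -> tuple[np.ndarray, list[float]]:
    """Iteratively reweighted least squares for a log-link power-variance GLM.

    Working weights are mu^(2-p) (expected information), the working
    response is eta + (y - mu)/mu.  Step-halving on the quasi-deviance and a
    clipped linear predictor keep the iteration stable under the extreme
    right tails healthcare costs exhibit.  Returns (coefficients, deviance
    trace); raises :class:`ConvergenceError` if the stopping rule
    (relative deviance change below ``tol``) is not met in ``max_iter``
    iterations.
    """
    p = FAMILY_POWER[family]
    n, k = exog.shape
    if start is None:
        start = np.linalg.lstsq(exog, np.log(y), rcond=None)[0]
    beta = np.asarray(start, dtype=float)

    def dev_of(b):
        eta = np.clip(exog @ b, -_ETA_CLIP, _ETA_CLIP)
        return _quasi_deviance(y, np.exp(eta), p), eta

    dev, eta = dev_of(beta)
    trace = [dev]
    for _ in range(max_iter):
        mu = np.exp(eta)
        w = mu ** (2 - p)
        z = eta + (y - mu) / mu
        sw = np.sqrt(w)
        step, *_ = np.linalg.lstsq(exog * sw[:, None], z * sw, rcond=None)
        # step-halving: never accept an update that increases the deviance
        direction = step - beta
        lam = 1.0
        for _half in range(40):
            cand = beta + lam * direction
            dev_new, eta_new = dev_of(cand)
            if np.isfinite(dev_new) and dev_new <= dev + 1e-12 * abs(dev):
                break
            lam /= 2.0
        else:
            # no descent direction left: numerically stationary
            return beta, trace
        beta, eta = cand, eta_new
        trace.append(dev_new)
        if abs(dev - dev_new) <= tol * (abs(dev_new) + 0.1):
            return beta, trace
        dev = dev_new
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations", trace=trace)


def glm_sandwich_vcov(exog: np.ndarray, y: np.ndarray, mu: np.ndarray,
                      family: str) -> np.ndarray:
    """Huber-White covariance for a log-link GLM (HC0 form).

    Bread is the inverse expected information ``(X' W X)^{-1}`` with working
    weights ``w = mu^2 / V(mu)``; meat is ``X' diag(s^2) X`` with score
    residuals ``s = (y - mu) mu / V(mu)``.  The dispersion cancels.
    """
    p = FAMILY_POWER[family]
    V = mu ** p
    w = mu**2 / V
    bread = np.linalg.inv(exog.T @ (exog * w[:, None]))
    s = (y - mu) * mu / V
    meat = exog.T @ (exog * (s**2)[:, None])
    vc = bread @ meat @ bread
    return (vc + vc.T) / 2.0


def ols_sandwich_vcov(exog: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Textbook HC0: ``(X'X)^{-1} X' diag(e^2) X (X'X)^{-1}``."""
    bread = np.linalg.inv(exog.T @ exog)
    meat = exog.T @ (exog * (resid**2)[:, None])
    vc = bread @ meat @ bread
    return (vc + vc.T) / 2.0


class GLMCostModel(BaseEstimator, RegressorMixin):
    """Log-link GLM for positive costs under a power variance function.

    Parameters
    ----------
    family : {"gaussian", "poisson", "gamma", "inverse_gaussian"}
        Variance function V(mu) = mu^lambda with lambda = 0, 1, 2, 3.
    max_iter, tol
        IRLS stopping rule: relative deviance change below ``tol`` or
        ``max_iter`` iterations (non-convergence raises
        :class:`~costlines.exceptions.ConvergenceError`).

    X never includes an intercept column; the intercept is fitted internally
    and exposed as ``intercept_``.  Dispersion for the non-Gaussian families
    is the Pearson moment estimate (affects standard errors only).
    """

    def __init__(self, family: str = "gamma", max_iter: int = 100,
                 tol: float = 1e-8):
        self.family = family
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        if self.family not in GLM_FAMILIES:
            raise ValueError(f"unknown variance family {self.family!r}")
        Xa, y, names = _check_Xy(X, y, require_positive=True)
        exog = np.column_stack([np.ones(len(y)), Xa])
        # log-link power-variance fits are scale-equivariant: fitting on
        # y / geometric-mean only shifts the intercept by log(c), so heavy
        # right tails can be tamed before IRLS sees them
        log_c = float(np.mean(np.log(y)))
        ys = y * np.exp(-log_c)
        params, trace = irls_log_link(exog, ys, self.family,
                                      max_iter=self.max_iter, tol=self.tol)
        params = params.copy()
        params[0] += log_c            # undo the internal rescaling
        self.fit_trace_ = trace
        self.intercept_ = float(params[0])
        self.coef_ = params[1:]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xa.shape[1]
        self.column_names_ = ("const",) + tuple(names)
        self.linear_predictor_ = exog @ params
        self.fitted_mean_ = np.exp(self.linear_predictor_)
        self.resid_raw_ = y - self.fitted_mean_
        self.resid_log_ = np.log(y) - self.linear_predictor_
        mu = self.fitted_mean_
        p = FAMILY_POWER[self.family]
        # Pearson moment estimate of the dispersion (affects SEs only)
        dof = max(len(y) - exog.shape[1], 1)
        self.dispersion_ = float(np.sum((y - mu) ** 2 / mu**p) / dof)
        w = mu ** (2 - p)
        info = exog.T @ (exog * w[:, None])
        vc = self.dispersion_ * np.linalg.inv(info)
        self.vcov_ = (vc + vc.T) / 2.0
        self.robust_vcov_ = glm_sandwich_vcov(exog, y, mu, self.family)
        self.n_obs_ = len(y)
        return self

    def predict(self, X):
        Xa, _, _ = _check_Xy(X, np.ones(np.shape(X)[0]),
                             require_positive=False)
        return np.exp(self.intercept_ + Xa @ self.coef_)

    def to_fitted_model(self) -> FittedModel:
        return FittedModel(
            branch="GLM", family=self.family, alpha=self.intercept_,
            beta=self.coef_.copy(), vcov_model=self.vcov_,
            vcov_robust=self.robust_vcov_, eta=self.linear_predictor_,
            mu=self.fitted_mean_, resid_raw=self.resid_raw_,
            resid_log=self.resid_log_, n=self.n_obs_,
            dispersion=self.dispersion_, column_names=self.column_names_)


class LogOLSCostModel(BaseEstimator, RegressorMixin):
    """OLS on log costs with a configurable EUR-scale retransformation.

    Parameters
    ----------
    retransform : {"duan", "normal_hetero", "none"}
        ``duan``: multiply exp(eta) by the smearing factor
        mean(exp(residual)).  ``normal_hetero``: fit a secondary variance
        model on log squared residuals and use exp(eta + v(x)/2) per row.
        ``none``: predict exp(eta) uncorrected (log-scale geometric mean).
    """

    def __init__(self, retransform: str = "duan"):
        self.retransform = retransform

    def fit(self, X, y):
        if self.retransform not in ("duan", "normal_hetero", "none"):
            raise ValueError(f"unknown retransform {self.retransform!r}")
        Xa, y, names = _check_Xy(X, y, require_positive=True)
        exog = np.column_stack([np.ones(len(y)), Xa])
        res = sm.OLS(np.log(y), exog).fit()
        params = np.asarray(res.params, dtype=float)
        self.intercept_ = float(params[0])
        self.coef_ = params[1:]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xa.shape[1]
        self.column_names_ = ("const",) + tuple(names)
        self.linear_predictor_ = np.asarray(res.fittedvalues)
        self.resid_log_ = np.asarray(res.resid)
        self.vcov_ = np.asarray(res.cov_params())
        self.robust_vcov_ = ols_sandwich_vcov(exog, self.resid_log_)
        self.n_obs_ = len(y)
        self.sigma2_ = float(self.resid_log_ @ self.resid_log_
                             / max(self.n_obs_ - exog.shape[1], 1))
        self.smearing_factor_ = float(np.mean(np.exp(self.resid_log_)))
        if self.retransform == "normal_hetero":
            self.variance_model_ = fit_variance_model_arrays(
                self.resid_log_, exog, self.column_names_)
        else:
            self.variance_model_ = None
        self.fitted_mean_ = self._retransformed(exog,
                                                self.linear_predictor_)
        self.resid_raw_ = y - self.fitted_mean_
        self._res = res
        return self

    def _retransformed(self, exog: np.ndarray,
                       eta: np.ndarray) -> np.ndarray:
        if self.retransform == "none":
            return np.exp(eta)
        if self.retransform == "duan":
            return np.exp(eta) * self.smearing_factor_
        v = self.variance_model_.predict_variance(exog)
        return np.exp(eta + v / 2.0)

    def predict(self, X):
        Xa, _, _ = _check_Xy(X, np.ones(np.shape(X)[0]),
                             require_positive=False)
        exog = np.column_stack([np.ones(Xa.shape[0]), Xa])
        eta = self.intercept_ + Xa @ self.coef_
        return self._retransformed(exog, eta)

    def to_fitted_model(self) -> FittedModel:
        return FittedModel(
            branch="LOG_OLS", family=None, alpha=self.intercept_,
            beta=self.coef_.copy(), vcov_model=self.vcov_,
            vcov_robust=self.robust_vcov_, eta=self.linear_predictor_,
            mu=self.fitted_mean_, resid_raw=self.resid_raw_,
            resid_log=self.resid_log_, n=self.n_obs_,
            dispersion=self.sigma2_, column_names=self.column_names_)


# ---------------------------------------------------------------------------
# functional surface over DesignMatrix


def fit_glm_log(design: DesignMatrix, y, family: str = "gamma",
                max_iter: int = 100, tol: float = 1e-8) -> FittedModel:
    """Fit a log-link GLM on a positive-cost design (see GLMCostModel)."""
    est = GLMCostModel(family=family, max_iter=max_iter, tol=tol)
    est.fit(design.covariates, y)
    m = est.to_fitted_model()
    m.column_names = design.column_names
    return m


def fit_log_ols(design: DesignMatrix, y) -> FittedModel:
    """OLS on log costs; EUR-scale mu left unset until retransformation."""
    est = LogOLSCostModel(retransform="none")
    est.fit(design.covariates, y)
    m = est.to_fitted_model()
    m.column_names = design.column_names
    m.mu = None          # requires an explicit retransformation choice
    m.resid_raw = None
    return m


def huber_white_vcov(model: FittedModel, design: DesignMatrix) -> np.ndarray:
    """Huber-White sandwich covariance for a fitted model on its design."""
    exog = design.exog
    if exog.shape[0] != model.n:
        raise ValueError("design does not match the fitted model")
    if model.branch == "LOG_OLS":
        return ols_sandwich_vcov(exog, model.resid_log)
    mu = np.exp(model.eta)
    y = mu + (model.resid_raw if model.resid_raw is not None else 0.0)
    return glm_sandwich_vcov(exog, y, mu, model.family)


def fit_variance_model_arrays(resid_log: np.ndarray, exog: np.ndarray,
                              column_names=()) -> VarianceModel:
    """Secondary regression of log squared residuals on the design."""
    e = np.asarray(resid_log, dtype=float).copy()
    zero = e == 0.0
    n_zero = int(zero.sum())
    if n_zero:
        nonzero = np.abs(e[~zero])
        if nonzero.size == 0:
            raise ValueError("all residuals are exactly zero")
        e[zero] = nonzero.min()
        warnings.warn(f"replaced {n_zero} zero residuals by the smallest "
                      "positive |residual| before taking logs")
    logsq = np.log(e**2)
    res = sm.OLS(logsq, exog).fit()
    gamma = np.asarray(res.params, dtype=float)
    raw = np.exp(exog @ gamma)
    mean_sq = float(np.mean(np.asarray(resid_log, dtype=float) ** 2))
    calibration = mean_sq / float(np.mean(raw))
    return VarianceModel(gamma=gamma, calibration=calibration,
                         resid_var=float(res.mse_resid),
                         column_names=tuple(column_names),
                         n_zero_replaced=n_zero)


def fit_variance_model(model: FittedModel,
                       design: DesignMatrix) -> VarianceModel:
    """Variance model for a log-OLS fit (heteroscedastic retransformation)."""
    if model.branch != "LOG_OLS":
        raise ValueError("variance model is defined for the LOG_OLS branch")
    return fit_variance_model_arrays(model.resid_log, design.exog,
                                     design.column_names)


def predict_mean(model: FittedModel, design: DesignMatrix,
                 method: str = "duan",
                 varmodel: VarianceModel | None = None) -> np.ndarray:
    """EUR-scale conditional-mean predictions per row.

    GLM branch (``method="none"``): exp(eta).  LOG_OLS with ``duan``:
    exp(eta) times the smearing factor mean(exp(residual)).  LOG_OLS with
    ``normal_hetero``: exp(eta + v(x)/2) with v from the variance model.
    """
    eta = design.exog @ model.params
    if method == "none":
        if model.branch != "GLM":
            raise ValueError("method 'none' is only valid for the GLM branch")
        return np.exp(eta)
    if model.branch != "LOG_OLS":
        raise ValueError(f"method {method!r} requires the LOG_OLS branch")
    if method == "duan":
        factor = float(np.mean(np.exp(model.resid_log)))
        return np.exp(eta) * factor
    if method == "normal_hetero":
        if varmodel is None:
            raise ValueError("normal_hetero requires a fitted VarianceModel")
        v = varmodel.predict_variance(design.exog)
        return np.exp(eta + v / 2.0)
    raise ValueError(f"unknown retransformation method {method!r}")
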