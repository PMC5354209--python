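"""Decision statistics and the robustness battery.

The routing statistics (raw kurtosis of log-scale residuals, the kurtosis
decision map, the GLM Park test with its nearest-integer variance-family
map) and the robustness tests (modified Hosmer-Lemeshow F-test on
fitted-value deciles, MAPE/MEDAPE accuracy, Pregibon link test,
Breusch-Pagan heteroscedasticity test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .design import DesignMatrix
from .exceptions import DegenerateDataError
from .models import FittedModel, fit_glm_log

#: Park-test slope -> variance family, by nearest integer in [0, 3].
LAMBDA_FAMILIES = ("gaussian", "poisson", "gamma", "inverse_gaussian")

#: Kurtosis thresholds of the decision rule: "about 3" routes to a GLM, with
#: a borderline band up to 3.25 flagged for inspection of the precision
#: statistics; at or above 3.25 the heavy-tail branch (log-OLS) is taken.
TAU_LOW, TAU_HIGH = 3.0, 3.25


@dataclass
class ParkResult:
    lam: float
    se: float
    family: str

    def to_dict(self) -> dict:
        return {"lambda": self.lam, "se": self.se, "family": self.family}


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: tuple | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"name": self.name, "statistic": self.statistic,
                "p_value": self.p_value, "df": self.df, **self.extra}


def kurtosis(v, excess: bool = False) -> float:
    """Pearson kurtosis m4 / m2^2 (population moments; normal reference 3).

    ``excess=True`` subtracts 3; the decision rule always uses the raw form.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 4:
        raise ValueError("kurtosis requires at least 4 observations")
    if not np.all(np.isfinite(v)):
        raise ValueError("kurtosis requires finite values")
    if np.var(v) == 0:
        raise DegenerateDataError("kurtosis undefined for zero variance")
    k = float(stats.kurtosis(v, fisher=False, bias=True))
    return k - 3.0 if excess else k


def choose_model_class(k: float, tau_low: float = TAU_LOW,
                       tau_high: float = TAU_HIGH) -> tuple[str, bool]:
    """Route on log-residual kurtosis: (branch, borderline flag).

    k <= tau_low: GLM.  tau_low < k < tau_high: GLM, borderline (precision
    statistics must be inspected).  k >= tau_high: heavy-tailed, log-OLS.
    """
    if tau_low > tau_high:
        raise ValueError("tau_low must be <= tau_high")
    if k >= tau_high:
        return "LOG_OLS", False
    return "GLM", k > tau_low


def family_from_lambda(lam: float) -> str:
    """Nearest-integer map of the Park slope onto a variance family.

    lambda is clamped to [0, 3]; half-integer ties round toward the
    higher-variance family.
    """
    lam = min(max(float(lam), 0.0), 3.0)
    idx = int(np.floor(lam + 0.5))
    return LAMBDA_FAMILIES[min(idx, 3)]


def park_test(y, mu, variant: str = "glm") -> ParkResult:
    """GLM Park test: slope of (y - mu)^2 on log(mu).

    The default variant regresses the squared raw-scale residuals on the log
    fitted values through a log-link quasi-likelihood (gamma) regression; the
    slope lambda indexes the variance power law V(mu) = mu^lambda.  The
    ``ols_log`` variant regresses log squared residuals by OLS instead.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have the same length")
    if np.any(mu <= 0):
        raise ValueError("fitted means must be strictly positive")
    r2 = (y - mu) ** 2
    if np.all(r2 == 0):
        raise DegenerateDataError("all residuals are zero; Park slope "
                                  "undefined")
    exog = np.column_stack([np.ones(len(y)), np.log(mu)])
    if variant == "glm":
        from .models import irls_log_link

        r2c = np.maximum(r2, r2[r2 > 0].min() * 1e-12)
        # gamma-family quasi-likelihood (squared residuals have variance on
        # the scale of their squared mean); slope is scale-equivariant
        log_c = float(np.mean(np.log(r2c)))
        r2s = r2c * np.exp(-log_c)
        params, _ = irls_log_link(exog, r2s, "gamma")
        fitted = np.exp(np.clip(exog @ params, -250, 250))
        dof = max(len(y) - 2, 1)
        phi = float(np.sum(((r2s - fitted) / fitted) ** 2) / dof)
        vcov = phi * np.linalg.inv(exog.T @ exog)
        lam, se = float(params[1]), float(np.sqrt(vcov[1, 1]))
    elif variant == "ols_log":
        tiny = r2[r2 > 0].min() * 1e-12
        res = sm.OLS(np.log(np.maximum(r2, tiny)), exog).fit()
        lam, se = float(res.params[1]), float(res.bse[1])
    else:
        raise ValueError(f"unknown Park variant {variant!r}")
    return ParkResult(lam=lam, se=se, family=family_from_lambda(lam))


def modified_hl_test(resid_raw, mu, groups: int = 10) -> TestResult:
    """Modified Hosmer-Lemeshow F-test for systematic bias across deciles.

    Rows are ranked by fitted mean and cut into ``groups`` quantile bins
    (ties broken by stable row order); raw-scale residuals are regressed on
    the bin indicators without an intercept and the joint null that every
    bin mean is zero is tested with the OLS F-test (df = groups,
    n - groups).  Bins with fewer than 2 rows trigger a reduction of
    ``groups``.
    """
    resid = np.asarray(resid_raw, dtype=float)
    mu = np.asarray(mu, dtype=float)
    n = len(resid)
    if n != len(mu):
        raise ValueError("residuals and fitted means must align")
    if n < 4:
        raise ValueError("need at least 2 groups of 2 rows")
    order = np.argsort(mu, kind="stable")
    while True:
        edges = (np.arange(1, groups) * n) // groups
        bins = np.zeros(n, dtype=int)
        bins[order] = np.searchsorted(edges, np.arange(n), side="right")
        counts = np.bincount(bins, minlength=groups)
        if counts.min() >= 2:
            break
        if groups <= 2:
            raise ValueError("cannot form 2 groups of at least 2 rows")
        warnings.warn(f"bin with < 2 rows; reducing groups to {groups - 1}")
        groups -= 1
    if np.all(resid == 0):
        return TestResult("modified_hl", 0.0, 1.0, (groups, n - groups))
    dummies = np.eye(groups)[bins]
    res = sm.OLS(resid, dummies).fit()
    wald = res.wald_test(np.eye(groups), use_f=True, scalar=True)
    return TestResult("modified_hl", float(wald.statistic),
                      float(wald.pvalue), (groups, n - groups),
                      extra={"groups": groups})


def mape_medape(y, yhat) -> tuple[float, float]:
    """Mean and median absolute percentage error, as proportions.

    PE_i = (y_i - yhat_i) / y_i; the denominator is the observed cost, which
    is strictly positive for the positive-cost models.  MEDAPE is robust to
    the outliers that inflate MAPE.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    if np.any(y == 0):
        raise ValueError("MAPE/MEDAPE undefined when an observed y is 0")
    ape = np.abs((y - yhat) / y)
    return float(np.mean(ape)), float(np.median(ape))


def pregibon_link_test(model: FittedModel, design: DesignMatrix,
                       y) -> TestResult:
    """Pregibon link test for the log-link specification of a GLM.

    Refits the same-family GLM on the fitted linear predictor and its
    square; the statistic is the coefficient of eta^2 with its Wald p-value
    (a significant square term indicates link misspecification).
    """
    if model.branch != "GLM":
        raise ValueError("the link test applies to the GLM branch")
    eta = np.asarray(model.eta, dtype=float)
    if np.ptp(eta) == 0:
        raise DegenerateDataError("constant linear predictor; link test "
                                  "undefined")
    y = np.asarray(y, dtype=float)
    # center eta to keep eta and eta^2 well conditioned
    c = eta.mean()
    z = eta - c
    aux = DesignMatrix(
        X=pd.DataFrame({"const": np.ones(len(y)), "eta": z, "eta2": z**2}),
        column_names=("const", "eta", "eta2"))
    refit = fit_glm_log(aux, y, family=model.family)
    coef = float(refit.beta[1])
    se = float(np.sqrt(refit.vcov_model[2, 2]))
    if se == 0.0:
        zstat = 0.0 if coef == 0.0 else np.inf * np.sign(coef)
    else:
        zstat = coef / se
    p = 2.0 * stats.norm.sf(abs(zstat))
    return TestResult("pregibon_link", coef, float(p),
                      extra={"coef": coef, "se": se, "z": zstat})


def breusch_pagan(model: FittedModel,
                  design: DesignMatrix) -> TestResult:
    """Koenker's studentized Breusch-Pagan test on a log-OLS fit.

    LM = n R^2 from the auxiliary regression of squared OLS residuals on the
    design; p from chi-square with df = number of non-intercept columns.
    """
    if model.branch != "LOG_OLS":
        raise ValueError("the Breusch-Pagan test applies to the LOG_OLS "
                         "branch")
    exog = design.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = np.asarray(model.resid_log, dtype=float)
    df = exog.shape[1] - 1
    if np.ptp(resid**2) == 0:
        # constant squared residuals: nothing for the auxiliary fit to find
        return TestResult("breusch_pagan", 0.0, 1.0, (df,))
    lm, lm_p, _, _ = het_breuschpagan(resid, exog, robust=True)
    return TestResult("breusch_pagan", float(lm), float(lm_p), (df,))
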