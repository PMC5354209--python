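"""The model-selection algorithm, end to end.

For each service line the pipeline: (1) fits a preliminary log-link
GLM-gamma on positive costs; (2) measures the raw kurtosis of the log-scale
residuals; (3) keeps the GLM class when the residuals are not heavy-tailed
(kurtosis about 3 or less) and otherwise switches to OLS on log costs;
(4) on the GLM branch, runs the Park test and refits under the selected
variance family, then checks the fit with the modified Hosmer-Lemeshow
F-test, MAPE/MEDAPE and the Pregibon link test; on the log-OLS branch, runs
the same accuracy checks plus the Breusch-Pagan test and, when the latter
rejects, switches to Huber-White standard errors and a heteroscedastic
retransformation driven by a secondary variance model; (5) reports the
multiplicative effects exp(beta) against the baselines (female, "1-0"
Healthy) with significance at 0.05.

:class:`ManningMullahySelector` packages steps (1)-(4) as a scikit-learn
estimator; :func:`run_algorithm` / :func:`run_all_lines` drive it from a
cohort table and assemble the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from . import __version__ as _pkg_version
from .design import DesignMatrix, build_design
from .diagnostics import (TAU_HIGH, TAU_LOW, ParkResult, TestResult,
                          breusch_pagan, choose_model_class, kurtosis,
                          mape_medape, modified_hl_test, park_test,
                          pregibon_link_test)
from .exceptions import EmptyDataError
from .models import (FittedModel, GLMCostModel, LogOLSCostModel,
                     VarianceModel, fit_variance_model_arrays)

logger = logging.getLogger("costlines")


@dataclass
class PipelineOptions:
    """Tunable knobs of the selection pipeline (defaults are the method's)."""

    tau_low: float = TAU_LOW
    tau_high: float = TAU_HIGH
    hl_groups: int = 10
    alpha: float = 0.05
    min_n: int = 50
    park_variant: str = "glm"
    hl_on_log_scale: bool = False   # for log-OLS rows: HL on log residuals
    max_iter: int = 100
    tol: float = 1e-8


@dataclass
class DiagnosticsRow:
    """One report row per service line (the diagnostics-table schema)."""

    line: str
    n: int
    kurtosis: float
    model: str                      # "GLM" or "Log-ols"
    park_lambda: float | None
    family: str | None
    hl: TestResult
    mape: float
    medape: float
    pregibon: TestResult | None
    bp: TestResult | None

    def to_dict(self) -> dict:
        return {
            "line": self.line, "N": self.n, "kurtosis": self.kurtosis,
            "model": self.model,
            "park": self.park_lambda, "distribution": self.family,
            "hl_F": self.hl.statistic, "hl_p": self.hl.p_value,
            "mape": self.mape, "medape": self.medape,
            "pregibon_coef": None if self.pregibon is None
            else self.pregibon.statistic,
            "pregibon_p": None if self.pregibon is None
            else self.pregibon.p_value,
            "bp_stat": None if self.bp is None else self.bp.statistic,
            "bp_p": None if self.bp is None else self.bp.p_value,
        }


@dataclass
class SelectionResult:
    """Final model for one line plus diagnostics, effects and flags."""

    row: DiagnosticsRow
    model: FittedModel
    effects: dict[str, tuple[float, float, bool]]
    flags: dict[str, bool]
    varmodel: VarianceModel | None = None
    design: DesignMatrix | None = None
    predicted_mean: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "row": self.row.to_dict(),
            "coefficients": dict(zip(self.model.column_names,
                                     self.model.params.tolist())),
            "effects": {t: {"exp_beta": e, "p": p, "significant": s}
                        for t, (e, p, s) in self.effects.items()},
            "flags": dict(self.flags),
        }


class ManningMullahySelector(BaseEstimator, RegressorMixin):
    """Kurtosis-routed choice between a log-link GLM and OLS on log costs.

    Fit on a positive-cost design (no intercept column; covariates age,
    male and ACRG3 indicators, or anything else — the router is generic).
    After ``fit`` the chosen branch and its full diagnostics battery are
    available as fitted attributes, and ``predict`` returns EUR-scale
    conditional means under the branch's retransformation.

    Parameters mirror :class:`PipelineOptions`: the kurtosis thresholds, the
    number of Hosmer-Lemeshow bins, the significance level used both for the
    heteroscedasticity switch and for the effects table, and the Park-test
    variant.
    """

    def __init__(self, tau_low: float = TAU_LOW, tau_high: float = TAU_HIGH,
                 hl_groups: int = 10, alpha: float = 0.05,
                 park_variant: str = "glm", hl_on_log_scale: bool = False,
                 max_iter: int = 100, tol: float = 1e-8):
        self.tau_low = tau_low
        self.tau_high = tau_high
        self.hl_groups = hl_groups
        self.alpha = alpha
        self.park_variant = park_variant
        self.hl_on_log_scale = hl_on_log_scale
        self.max_iter = max_iter
        self.tol = tol

    # -- algorithm ---------------------------------------------------------
    def fit(self, X, y, line: str = ""):
        y = np.asarray(y, dtype=float).ravel()

        # (1) preliminary GLM-gamma with log link
        prelim = GLMCostModel(family="gamma", max_iter=self.max_iter,
                              tol=self.tol).fit(X, y)
        # (2) kurtosis of the log-scale residuals
        self.kurtosis_ = kurtosis(prelim.resid_log_)
        # (3) route on kurtosis
        self.branch_, self.borderline_ = choose_model_class(
            self.kurtosis_, self.tau_low, self.tau_high)
        logger.info("%s: kurtosis=%.3f (tau=%.2f/%.2f) -> %s%s",
                    line or "<line>", self.kurtosis_, self.tau_low,
                    self.tau_high, self.branch_,
                    " [borderline]" if self.borderline_ else "")

        self.park_: ParkResult | None = None
        self.pregibon_: TestResult | None = None
        self.bp_: TestResult | None = None
        self.varmodel_: VarianceModel | None = None
        self.heteroscedastic_ = False

        if self.branch_ == "GLM":
            # (4a) Park test on the preliminary fit, refit with that family
            self.park_ = park_test(y, prelim.fitted_mean_,
                                   variant=self.park_variant)
            self.family_ = self.park_.family
            logger.info("%s: Park lambda=%.3f -> %s", line or "<line>",
                        self.park_.lam, self.family_)
            if self.family_ == "gamma":
                final = prelim
            else:
                final = GLMCostModel(family=self.family_,
                                     max_iter=self.max_iter,
                                     tol=self.tol).fit(X, y)
            self.estimator_ = final
            fitted = final.to_fitted_model()
            self.predicted_mean_ = final.fitted_mean_
            self.pregibon_ = pregibon_link_test(
                fitted, _design_from(X, include_const=True), y)
        else:
            # (4b) heavy tails: OLS on log costs
            ols = LogOLSCostModel(retransform="duan").fit(X, y)
            fitted = ols.to_fitted_model()
            design = _design_from(X, include_const=True)
            self.bp_ = breusch_pagan(fitted, design)
            self.heteroscedastic_ = self.bp_.p_value < self.alpha
            logger.info("%s: Breusch-Pagan LM=%.2f p=%.3g -> %s",
                        line or "<line>", self.bp_.statistic,
                        self.bp_.p_value,
                        "heteroscedastic" if self.heteroscedastic_
                        else "homoscedastic")
            if self.heteroscedastic_:
                ols = LogOLSCostModel(retransform="normal_hetero").fit(X, y)
                fitted = ols.to_fitted_model()
                self.varmodel_ = ols.variance_model_
            self.estimator_ = ols
            self.family_ = None
            self.predicted_mean_ = ols.fitted_mean_

        self.model_ = fitted
        resid_for_hl = (fitted.resid_log if (self.branch_ == "LOG_OLS"
                                             and self.hl_on_log_scale)
                        else y - self.predicted_mean_)
        mu_for_hl = (fitted.eta if (self.branch_ == "LOG_OLS"
                                    and self.hl_on_log_scale)
                     else self.predicted_mean_)
        self.hl_ = modified_hl_test(resid_for_hl, mu_for_hl,
                                    groups=self.hl_groups)
        self.mape_, self.medape_ = mape_medape(y, self.predicted_mean_)
        self.flags_ = {
            "borderline_kurtosis": bool(self.borderline_),
            "heteroscedastic": bool(self.heteroscedastic_),
            "link_misspecified": bool(
                self.pregibon_ is not None
                and self.pregibon_.p_value < self.alpha),
            "hl_failed": bool(self.hl_.p_value < self.alpha),
        }
        self.n_obs_ = len(y)
        return self

    def predict(self, X):
        return self.estimator_.predict(X)

    # -- reporting ---------------------------------------------------------
    def effects(self) -> dict[str, tuple[float, float, bool]]:
        """Multiplicative effects exp(beta) with p-values at ``alpha``.

        Uses the Huber-White covariance on the log-OLS branch (model-based
        p-values are unreliable under heteroscedasticity) and the
        model-based covariance on the GLM branch.
        """
        return effects_table(self.model_, alpha=self.alpha)

    def diagnostics_row(self, line: str = "") -> DiagnosticsRow:
        return DiagnosticsRow(
            line=line, n=self.n_obs_, kurtosis=self.kurtosis_,
            model="GLM" if self.branch_ == "GLM" else "Log-ols",
            park_lambda=None if self.park_ is None else self.park_.lam,
            family=self.family_, hl=self.hl_, mape=self.mape_,
            medape=self.medape_, pregibon=self.pregibon_, bp=self.bp_)


def _design_from(X, include_const: bool = True) -> DesignMatrix:
    if isinstance(X, pd.DataFrame):
        Xd = X.copy()
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        Xd = pd.DataFrame(Xa, columns=[f"x{i}" for i in range(Xa.shape[1])])
    if include_const:
        Xd.insert(0, "const", 1.0)
    return DesignMatrix(X=Xd, column_names=tuple(Xd.columns))


def effects_table(model: FittedModel,
                  alpha: float = 0.05) -> dict[str, tuple[float, float, bool]]:
    """Per-term multiplicative effects exp(beta): (effect, p, significant).

    Baseline levels (female, the baseline morbidity category) are implicit
    1.0 and absent from the map; the age effect is per year of age.  The
    p-value comes from the robust covariance for log-OLS fits and from the
    model-based covariance for GLM fits, Wald-normal.
    """
    robust = model.branch == "LOG_OLS"
    se = model.se(robust=robust)
    out: dict[str, tuple[float, float, bool]] = {}
    names = model.column_names or tuple(
        f"x{i}" for i in range(len(model.params)))
    for i, name in enumerate(names):
        if name == "const":
            continue
        b = float(model.params[i])
        z = b / se[i] if se[i] > 0 else np.inf
        p = float(2.0 * stats.norm.sf(abs(z)))
        out[name] = (float(np.exp(b)), p, p < alpha)
    return out


def run_algorithm(cohort: pd.DataFrame, line: str,
                  options: PipelineOptions | None = None) -> SelectionResult:
    """Run the full selection algorithm for one service line of a cohort."""
    opt = options or PipelineOptions()
    design, y = build_design(cohort, line)
    if design.n < opt.min_n:
        raise EmptyDataError(
            f"line {line!r} has {design.n} positive-cost rows "
            f"(< min_n = {opt.min_n})")
    sel = ManningMullahySelector(
        tau_low=opt.tau_low, tau_high=opt.tau_high, hl_groups=opt.hl_groups,
        alpha=opt.alpha, park_variant=opt.park_variant,
        hl_on_log_scale=opt.hl_on_log_scale, max_iter=opt.max_iter,
        tol=opt.tol)
    sel.fit(design.covariates, y, line=line)
    model = sel.model_
    model.column_names = design.column_names
    return SelectionResult(
        row=sel.diagnostics_row(line), model=model, effects=sel.effects(),
        flags=sel.flags_, varmodel=sel.varmodel_, design=design,
        predicted_mean=sel.predicted_mean_)


def with_total_line(cohort: pd.DataFrame,
                    total_name: str = "total") -> pd.DataFrame:
    """Append a row-wise total-cost column across all service lines."""
    cost_cols = [c for c in cohort.columns if c.startswith("cost_")
                 and c != f"cost_{total_name}"]
    out = cohort.copy()
    out[f"cost_{total_name}"] = out[cost_cols].sum(axis=1)
    return out


def run_all_lines(cohort: pd.DataFrame,
                  options: PipelineOptions | None = None,
                  add_total: bool = True,
                  total_name: str = "total"
                  ) -> tuple[dict[str, SelectionResult], dict[str, str]]:
    """One SelectionResult per line, plus a synthesized total-cost line.

    Per-line failures are collected (line -> error message) and the run
    continues.
    """
    from .simulate import cohort_lines

    lines = cohort_lines(cohort)
    if not lines:
        raise EmptyDataError("cohort has no cost_<line> columns")
    if add_total and total_name not in lines:
        cohort = with_total_line(cohort, total_name)
        lines = lines + [total_name]
    results: dict[str, SelectionResult] = {}
    errors: dict[str, str] = {}
    for line in lines:
        try:
            results[line] = run_algorithm(cohort, line, options)
        except Exception as exc:  # noqa: BLE001 - collected per line
            logger.warning("line %s failed: %s", line, exc)
            errors[line] = f"{type(exc).__name__}: {exc}"
    return results, errors


def diagnostics_frame(results: dict[str, SelectionResult]) -> pd.DataFrame:
    """Assemble the diagnostics report table (one row per line)."""
    return pd.DataFrame([r.row.to_dict() for r in results.values()])


def write_report(results: dict[str, SelectionResult], out_dir,
                 errors: dict[str, str] | None = None,
                 options: PipelineOptions | None = None,
                 seed: int | None = None) -> None:
    """Write diagnostics.csv, effects_<line>.csv and run.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    diagnostics_frame(results).to_csv(out / "diagnostics.csv", index=False)
    for line, res in results.items():
        eff = pd.DataFrame(
            [{"term": t, "exp_beta": e, "p": p, "significant": s}
             for t, (e, p, s) in res.effects.items()])
        eff.to_csv(out / f"effects_{line}.csv", index=False)
    payload = {
        "results": {line: res.to_dict() for line, res in results.items()},
        "errors": errors or {},
        "options": vars(options or PipelineOptions()),
        "seed": seed,
        "versions": {"costlines": _pkg_version,
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    with open(out / "run.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
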