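"""Generator configuration: the data-generating truth of a synthetic cohort.

A :class:`GeneratorConfig` fully specifies the joint law of a synthetic
integrated-care population: the ACRG3 category mix, per-line probabilities of
being a user (positive cost), multiplicative cost effects of morbidity, sex
and age, the log-scale error family per service line, and a per-category
heteroscedasticity map.  Everything downstream (parameter-recovery oracles,
routing simulations) reads the truth from this object.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .catalog import BASELINE_ACRG3, table1_probs
from .exceptions import ConfigurationError

ERROR_FAMILIES = ("lognormal", "gamma", "log_t")


@dataclass
class ErrorSpec:
    """Log-scale multiplicative error law for one service line.

    family
        ``lognormal``: eps ~ N(0, sigma^2).
        ``gamma``: exp(eps) ~ Gamma(shape)/shape (mean exactly 1); sigma is
        ignored, the log-scale spread is set by ``shape``.
        ``log_t``: eps = sigma * t_df / sqrt(df/(df-2)), with the standardized
        t truncated to |t| <= tmax standard deviations so that E[exp(eps)]
        exists (an unbounded t has no moment generating function).
    """

    family: str = "lognormal"
    sigma: float = 1.0
    shape: float = 20.0
    df: float = 3.0
    tmax: float = 8.0

    def validate(self) -> None:
        if self.family not in ERROR_FAMILIES:
            raise ConfigurationError(f"unknown error family {self.family!r}")
        if self.family == "log_t" and not self.df > 2:
            raise ConfigurationError("log_t requires df > 2 (finite variance)")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if self.shape <= 0:
            raise ConfigurationError("gamma shape must be > 0")
        if self.tmax <= 0:
            raise ConfigurationError("log_t truncation must be > 0")


@dataclass
class GeneratorConfig:
    """Data-generating truth for a synthetic CRG-stratified cohort.

    Positive cost on line ``l`` for a person with category ``c``, sex ``s``
    and age ``a`` is::

        base_cost[l] * effect[c] * sex_effect**[s == male]
                     * age_slope**(a - age_center) * exp(eps)

    with ``eps`` drawn from ``error_family[l]`` and its log-scale SD scaled
    by ``hetero_coefs[c]``.  A person is a user of line ``l`` (positive cost)
    with probability ``use_prob[l][c]``, independently across lines given the
    category.
    """

    category_probs: dict[str, float] = field(default_factory=table1_probs)
    use_prob: dict[str, dict[str, float] | float] = field(default_factory=dict)
    base_cost: dict[str, float] = field(default_factory=lambda: {"total": 900.0})
    effect: dict[str, float] = field(default_factory=dict)
    sex_effect: float = 1.0
    age_slope: float = 1.0
    error_family: dict[str, ErrorSpec] = field(default_factory=dict)
    hetero_coefs: dict[str, float] = field(default_factory=dict)
    male_prob: float = 0.5
    age_mean: float = 42.0
    age_sd: float = 23.0
    age_range: tuple[float, float] = (0.0, 100.0)
    baseline: str = BASELINE_ACRG3
    seed: int = 0

    # -- derived views -----------------------------------------------------
    @property
    def lines(self) -> tuple[str, ...]:
        return tuple(self.base_cost)

    @property
    def catalog(self) -> tuple[str, ...]:
        return tuple(self.category_probs)

    def line_use_prob(self, line: str) -> dict[str, float]:
        """Use probability per category for one line (scalars broadcast)."""
        p = self.use_prob.get(line, 1.0)
        if isinstance(p, Mapping):
            return {c: float(p[c]) for c in self.catalog}
        return {c: float(p) for c in self.catalog}

    def line_effect(self, category: str) -> float:
        return float(self.effect.get(category, 1.0))

    def hetero(self, category: str) -> float:
        return float(self.hetero_coefs.get(category, 1.0))

    def line_error(self, line: str) -> ErrorSpec:
        return self.error_family.get(line, ErrorSpec())

    # -- validation --------------------------------------------------------
    def validate(self) -> "GeneratorConfig":
        probs = self.category_probs
        if not probs:
            raise ConfigurationError("category_probs is empty")
        if any(not (0.0 <= p <= 1.0) for p in probs.values()):
            raise ConfigurationError("category probabilities must be in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("category_probs must sum to 1 within 1e-9")
        catalog = set(self.catalog)
        for name, mapping in (("effect", self.effect),
                              ("hetero_coefs", self.hetero_coefs)):
            unknown = set(mapping) - catalog
            if unknown:
                raise ConfigurationError(
                    f"{name} refers to unknown ACRG3 labels {sorted(unknown)}")
        if any(e < 0 for e in self.effect.values()):
            raise ConfigurationError("multiplicative effects must be >= 0")
        if self.baseline in self.effect and self.effect[self.baseline] != 1.0:
            raise ConfigurationError(
                f"baseline {self.baseline!r} effect must equal exactly 1")
        if self.sex_effect < 0 or self.age_slope < 0:
            raise ConfigurationError("sex_effect and age_slope must be >= 0")
        for line in self.use_prob:
            if line not in self.base_cost:
                raise ConfigurationError(f"use_prob for unknown line {line!r}")
            for c, p in self.line_use_prob(line).items():
                if not (0.0 <= p <= 1.0):
                    raise ConfigurationError(
                        f"use_prob[{line!r}][{c!r}] outside [0, 1]")
            p = self.use_prob[line]
            if isinstance(p, Mapping):
                unknown = set(p) - catalog
                if unknown:
                    raise ConfigurationError(
                        f"use_prob[{line!r}] has unknown labels {sorted(unknown)}")
        for line, spec in self.error_family.items():
            if line not in self.base_cost:
                raise ConfigurationError(
                    f"error_family for unknown line {line!r}")
            spec.validate()
        if any(b <= 0 for b in self.base_cost.values()):
            raise ConfigurationError("base_cost must be > 0")
        if not (0.0 <= self.male_prob <= 1.0):
            raise ConfigurationError("male_prob must be in [0, 1]")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigurationError("age_range must be increasing")
        return self

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "error_family" in d:
            d["error_family"] = {
                line: spec if isinstance(spec, ErrorSpec) else ErrorSpec(**spec)
                for line, spec in d["error_family"].items()
            }
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _status_severity_effect(label: str) -> float:
    """Illustrative morbidity effect: multiplicative in status and severity.

    Chosen so effects span roughly 1 to a few hundred, matching the scale on
    which the most severe catastrophic category multiplies baseline cost by
    two orders of magnitude.
    """
    status, level = (int(x) for x in label.split("-"))
    status_mult = {1: 1.0, 2: 1.6, 3: 2.2, 4: 3.5, 5: 5.0, 6: 9.0,
                   7: 25.0, 8: 45.0, 9: 65.0}[status]
    return status_mult * 1.18 ** level


def _status_use_ramp(label: str, p_healthy: float, p_severe: float) -> float:
    """Use probability interpolated on the log-odds scale from the healthy
    level (status 1) to the catastrophic level (status 9)."""
    status = int(label.split("-")[0])
    lo = math.log(p_healthy / (1.0 - p_healthy))
    hi = math.log(p_severe / (1.0 - p_severe))
    z = lo + (hi - lo) * (status - 1) / 8.0
    return 1.0 / (1.0 + math.exp(-z))


# per line: base EUR cost, use probability for healthy, and for catastrophic
_LINE_BASE = {
    "acute_outpatient": (240.0, 0.25, 0.90),
    "acute_inpatient": (2100.0, 0.03, 0.60),
    "primary_care": (110.0, 0.68, 0.99),
    "pharmacy": (160.0, 0.45, 0.98),
    "high_cost_rx": (4200.0, 0.002, 0.25),
    "diagnostic_tests": (90.0, 0.30, 0.95),
    "emergencies": (130.0, 0.15, 0.60),
}


def table1_preset(target_user_fraction: float = 76_360 / 92_498,
                  seed: int = 0) -> GeneratorConfig:
    """Seven-service-line preset with the published category mix.

    Per-line use probabilities rise with health status; a single exponent is
    calibrated (deterministically, by bisection) so the expected fraction of
    individuals with any positive cost matches ``target_user_fraction``
    (default: the reference population's 76,360 / 92,498 users).
    """
    from scipy.optimize import brentq

    probs = table1_probs()
    cats = tuple(probs)
    base_use = {line: {c: _status_use_ramp(c, p1, p9) for c in cats}
                for line, (_, p1, p9) in _LINE_BASE.items()}

    def any_use(m: float) -> float:
        tot = 0.0
        for c in cats:
            none = 1.0
            for line in base_use:
                none *= (1.0 - base_use[line][c]) ** m
            tot += probs[c] * (1.0 - none)
        return tot

    m = brentq(lambda x: any_use(x) - target_user_fraction, 0.01, 20.0,
               xtol=1e-12)
    use_prob = {line: {c: 1.0 - (1.0 - base_use[line][c]) ** m for c in cats}
                for line in base_use}

    cfg = GeneratorConfig(
        category_probs=probs,
        use_prob=use_prob,
        base_cost={line: b for line, (b, *_p) in _LINE_BASE.items()},
        effect={c: (1.0 if c == BASELINE_ACRG3 else _status_severity_effect(c))
                for c in cats},
        sex_effect=0.87,
        age_slope=1.005,
        error_family={line: ErrorSpec("lognormal", sigma=1.0)
                      for line in _LINE_BASE},
        hetero_coefs={},
        male_prob=0.49,
        seed=seed,
    )
    return cfg.validate()


def _small_world(effects: dict[str, float], line: str,
                 error: ErrorSpec, hetero: dict[str, float] | None = None,
                 use_prob: float = 1.0, seed: int = 0) -> GeneratorConfig:
    k = len(effects)
    probs = {c: 1.0 / k for c in effects}
    s = sum(probs.values())
    probs = {c: p / s for c, p in probs.items()}
    # exact normalization: put the residual on the first category
    first = next(iter(probs))
    probs[first] += 1.0 - sum(probs.values())
    return GeneratorConfig(
        category_probs=probs,
        use_prob={line: use_prob},
        base_cost={line: 150.0},
        effect=dict(effects),
        sex_effect=0.9,
        age_slope=1.004,
        error_family={line: error},
        hetero_coefs=dict(hetero or {}),
        baseline="1-0",
        seed=seed,
    ).validate()


def gamma_world(seed: int = 0, shape: float = 20.0) -> GeneratorConfig:
    """Correctly specified GLM-gamma world: variance proportional to mu^2.

    The multiplicative error is a mean-one gamma, so a log-link gamma GLM is
    the true model.  Log residuals of a log-gamma are always slightly
    leptokurtic, so the shape is kept large enough that their kurtosis stays
    well below the log-OLS threshold.
    """
    return _small_world(
        {"1-0": 1.0, "5-1": 5.0, "6-2": 20.0, "7-3": 100.0, "3-1": 2.0},
        line="total", error=ErrorSpec("gamma", shape=shape), seed=seed)


def lognormal_world(seed: int = 0, sigma: float = 1.0,
                    hetero: dict[str, float] | None = None) -> GeneratorConfig:
    """Log-OLS world with normal log-scale errors, optionally heteroscedastic."""
    return _small_world(
        {"1-0": 1.0, "5-1": 5.0, "6-2": 20.0, "3-1": 2.0},
        line="total", error=ErrorSpec("lognormal", sigma=sigma),
        hetero=hetero, seed=seed)


def heavy_tail_world(seed: int = 0, df: float = 3.0,
                     hetero: dict[str, float] | None = None) -> GeneratorConfig:
    """Heavy-tailed heteroscedastic world that should route to log-OLS.

    Log-scale errors are truncated Student-t with df = 3 (finite-sample
    kurtosis far above 3.25) and, by default, the log-scale SD differs by
    half again across morbidity categories — enough for the
    heteroscedasticity test to reject essentially always at realistic
    sample sizes, while keeping the conditional means finite and sane.
    """
    if hetero is None:
        hetero = {"1-0": 1.0, "3-1": 1.0, "5-1": 1.25, "6-2": 1.5}
    return _small_world(
        {"1-0": 1.0, "5-1": 5.0, "6-2": 20.0, "3-1": 2.0},
        line="total", error=ErrorSpec("log_t", sigma=0.8, df=df),
        hetero=hetero, seed=seed)
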