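"""Synthetic CRG-stratified cohort generator.

Generates person-level tables (one row per individual: sex, age, ACRG3
morbidity category, annual EUR cost per service line) whose statistical
structure matches what individual healthcare cost models assume: a zero mass
of non-users per line, and right-skewed positive costs that are
multiplicative in morbidity, sex and age on the log scale, with a
configurable error family and category-driven heteroscedasticity.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .config import ErrorSpec, GeneratorConfig
from .exceptions import ConfigurationError

COHORT_COLUMNS = ("person_id", "sex", "age", "acrg3")


def age_center(config: GeneratorConfig) -> float:
    """Mean of the truncated-normal age law; the centering point of the
    multiplicative age effect (so the intercept is the cost at mean age)."""
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    return float(stats.truncnorm.mean(a, b, loc=config.age_mean,
                                      scale=config.age_sd))


def _standardized_trunc_t(rng: np.random.Generator, df: float, tmax: float,
                          size: int) -> np.ndarray:
    """Draws of t_df / sd(t_df), truncated to |.| <= tmax, via inverse CDF."""
    sd = math.sqrt(df / (df - 2.0))
    c = tmax * sd
    lo, hi = stats.t.cdf(-c, df), stats.t.cdf(c, df)
    u = rng.uniform(lo, hi, size=size)
    return stats.t.ppf(u, df) / sd


def _log_multiplier(rng: np.random.Generator, spec: ErrorSpec,
                    hetero: np.ndarray, n: int) -> np.ndarray:
    """Multiplicative error exp(eps) per row, log-scale SD scaled by hetero."""
    if spec.family == "lognormal":
        return np.exp(rng.normal(0.0, spec.sigma * hetero, size=n))
    if spec.family == "gamma":
        # mean-one gamma; scaling the log-scale SD by h is implemented as
        # shape/h^2 (Var(log Gamma(k)) = psi'(k) ~ 1/k), keeping the mean at 1
        shape = spec.shape / np.square(hetero)
        return rng.gamma(shape) / shape
    if spec.family == "log_t":
        t = _standardized_trunc_t(rng, spec.df, spec.tmax, n)
        return np.exp(spec.sigma * hetero * t)
    raise ConfigurationError(f"unknown error family {spec.family!r}")


def retransformation_moment(spec: ErrorSpec, hetero: float = 1.0) -> float:
    """E[exp(eps)] for one error spec: the exact smearing factor of the truth.

    lognormal: exp(sigma^2 h^2 / 2).  gamma: 1 (the multiplier is mean-one by
    construction).  log_t: numerical quadrature of exp(s x) against the
    truncated standardized-t density (the untruncated t has no MGF).
    """
    spec.validate()
    s = spec.sigma * hetero
    if spec.family == "lognormal":
        return math.exp(0.5 * s * s)
    if spec.family == "gamma":
        return 1.0
    df, sd = spec.df, math.sqrt(spec.df / (spec.df - 2.0))
    c = spec.tmax * sd
    mass = stats.t.cdf(c, df) - stats.t.cdf(-c, df)
    val, _ = integrate.quad(
        lambda x: math.exp(s * x / sd) * stats.t.pdf(x, df), -c, c,
        limit=200)
    return val / mass


def generate_cohort(config: GeneratorConfig, n: int,
                    seed: int | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort of ``n`` individuals.

    Per service line, an individual has a positive cost with probability
    ``use_prob[line][category]``; the positive cost is
    ``base * effect[cat] * sex_effect^male * age_slope^(age - mean age)
    * exp(eps)``.  Fully reproducible given the seed (``config.seed`` unless
    overridden).

    Returns a DataFrame with columns person_id, sex, age, acrg3 and one
    ``cost_<line>`` column per line; cost 0 means non-user of that line.
    """
    config.validate()
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    cats = np.array(config.catalog)
    probs = np.array([config.category_probs[c] for c in cats])
    lines = config.lines
    if n == 0:
        data = {"person_id": pd.Series([], dtype=np.int64),
                "sex": pd.Series([], dtype=object),
                "age": pd.Series([], dtype=float),
                "acrg3": pd.Series([], dtype=object)}
        for line in lines:
            data[f"cost_{line}"] = pd.Series([], dtype=float)
        return pd.DataFrame(data)

    cat_idx = rng.choice(len(cats), size=n, p=probs)
    acrg3 = cats[cat_idx]
    male = rng.random(n) < config.male_prob

    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)
    center = age_center(config)

    hetero = np.array([config.hetero(c) for c in cats])[cat_idx]
    effect = np.array([config.line_effect(c) for c in cats])[cat_idx]
    mean_pos_base = (effect
                     * np.where(male, config.sex_effect, 1.0)
                     * config.age_slope ** (age - center))

    data = {"person_id": np.arange(n, dtype=np.int64),
            "sex": np.where(male, "male", "female"),
            "age": age,
            "acrg3": acrg3}
    for line in lines:
        use_p = config.line_use_prob(line)
        p_row = np.array([use_p[c] for c in cats])[cat_idx]
        user = rng.random(n) < p_row
        mult = _log_multiplier(rng, config.line_error(line), hetero, n)
        cost = config.base_cost[line] * mean_pos_base * mult
        data[f"cost_{line}"] = np.where(user, cost, 0.0)
    return pd.DataFrame(data)


def true_expected_cost(config: GeneratorConfig,
                       profile: tuple[str, float, str],
                       line: str) -> float:
    """Exact generative conditional mean E[Y | X, Y > 0] for one profile.

    ``profile`` is (sex, age, acrg3).  Closed form for lognormal and gamma
    errors; quadrature for the truncated log-t (see
    :func:`retransformation_moment`).
    """
    config.validate()
    sex, age, cat = profile
    if sex not in ("female", "male"):
        raise ValueError(f"invalid sex {sex!r}")
    if cat not in config.catalog:
        raise ConfigurationError(f"unknown ACRG3 label {cat!r}")
    if line not in config.base_cost:
        raise ConfigurationError(f"unknown service line {line!r}")
    spec = config.line_error(line)
    moment = retransformation_moment(spec, config.hetero(cat))
    return (config.base_cost[line]
            * config.line_effect(cat)
            * (config.sex_effect if sex == "male" else 1.0)
            * config.age_slope ** (age - age_center(config))
            * moment)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Serialize a cohort as UTF-8 CSV with '.' decimal separator."""
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path, dtype={"sex": str, "acrg3": str})
    required = set(COHORT_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns {sorted(missing)}")
    return df


def cohort_lines(cohort: pd.DataFrame) -> list[str]:
    """Service line names present in a cohort table."""
    return [c[len("cost_"):] for c in cohort.columns if c.startswith("cost_")]
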