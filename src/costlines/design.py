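"""Design-matrix construction for positive-cost models.

Rows are restricted to individuals with a positive cost on the target line.
Covariates are age (continuous, untransformed), a male indicator (female
baseline) and one indicator per non-baseline ACRG3 category present in the
data (baseline "1-0" Healthy).  Categories with fewer than two positive-cost
rows are dropped with a warning and recorded on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import BASELINE_ACRG3
from .exceptions import EmptyDataError


@dataclass
class DesignMatrix:
    """Fixed-baseline design for one service line.

    ``X`` carries the intercept column ``const`` first; ``column_names``
    preserves the order.  ``dropped`` records (category, row count) pairs
    removed for having fewer than two rows.
    """

    X: pd.DataFrame
    column_names: tuple[str, ...]
    baseline_category: str = BASELINE_ACRG3
    dropped: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def exog(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    @property
    def covariates(self) -> pd.DataFrame:
        """Design without the intercept column."""
        return self.X.iloc[:, 1:]


def build_design(cohort: pd.DataFrame, line: str,
                 baseline: str = BASELINE_ACRG3,
                 min_category_rows: int = 2) -> tuple[DesignMatrix, np.ndarray]:
    """Positive-cost design and response for one service line.

    Raises :class:`EmptyDataError` when no row has a positive cost on the
    line.  Degenerate categories (fewer than ``min_category_rows`` rows) and
    rows belonging to them are dropped with a warning so the design stays
    full rank.
    """
    col = f"cost_{line}"
    if col not in cohort.columns:
        raise KeyError(f"service line {line!r} not present in cohort")
    pos = cohort.loc[cohort[col] > 0].copy()
    if pos.empty:
        raise EmptyDataError(f"no positive costs on line {line!r}")

    dropped: list[tuple[str, int]] = []
    counts = pos["acrg3"].value_counts()
    small = counts[counts < min_category_rows]
    for cat, cnt in small.items():
        dropped.append((str(cat), int(cnt)))
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} ACRG3 categories with < "
            f"{min_category_rows} positive-cost rows on {line!r}: "
            f"{[c for c, _ in dropped]}")
        pos = pos[~pos["acrg3"].isin([c for c, _ in dropped])]
        if pos.empty:
            raise EmptyDataError(
                f"no positive costs left on line {line!r} after dropping "
                "degenerate categories")

    cats = sorted(c for c in pos["acrg3"].unique() if c != baseline)
    X = pd.DataFrame(index=pos.index)
    X["const"] = 1.0
    X["age"] = pos["age"].astype(float)
    X["male"] = (pos["sex"] == "male").astype(float)
    for c in cats:
        X[f"acrg3_{c}"] = (pos["acrg3"] == c).astype(float)

    # drop any residual zero-variance columns (e.g. single-sex selections)
    keep = ["const"] + [c for c in X.columns[1:] if X[c].nunique() > 1]
    X = X[keep]

    y = pos[col].to_numpy(dtype=float)
    design = DesignMatrix(X=X, column_names=tuple(X.columns),
                          baseline_category=baseline, dropped=dropped)
    return design, y
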