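"""Per-variable power transformation toward normality, plus standardization.

Steroid concentrations and molar ratios are positive and right-skewed, so
each variable is Box-Cox transformed before parametric analysis:

    y = (x^lambda - 1) / lambda      (lambda != 0)
    y = log(x)                       (lambda == 0)

lambda is chosen by exhaustive grid search (default [-3, 3] in steps of
0.01) maximizing a normality criterion of the transformed values:
Shapiro-Wilk W for n <= 50, and the (negated) Anderson-Darling statistic for
larger samples where W loses resolution.  The grid search is deterministic
and reproducible; after transformation each variable can be standardized to
mean 0, sd 1 (the scaling the discriminant model expects).

Transforms are fitted on patients and controls pooled, per variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableTransform",
    "TransformModel",
    "fit_power_transform",
    "fit_table",
    "apply_transform",
    "inverse_transform",
    "DEFAULT_GRID",
]

DEFAULT_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.01), 10)
_MIN_N = 8


@dataclass(frozen=True)
class VariableTransform:
    """Fitted Box-Cox parameters for one variable."""

    lambda_: float
    shift: float
    mean: float
    sd: float
    criterion: float  # normality score achieved at lambda_

    def forward(self, x: np.ndarray, standardize: bool = True) -> np.ndarray:
        xs = np.asarray(x, dtype=float) + self.shift
        with np.errstate(invalid="ignore"):
            if self.lambda_ == 0.0:
                y = np.log(xs)
            else:
                y = (np.power(xs, self.lambda_) - 1.0) / self.lambda_
        if standardize:
            y = (y - self.mean) / self.sd
        return y

    def inverse(self, y: np.ndarray, standardized: bool = True) -> np.ndarray:
        ys = np.asarray(y, dtype=float)
        if standardized:
            ys = ys * self.sd + self.mean
        if self.lambda_ == 0.0:
            x = np.exp(ys)
        else:
            x = np.power(ys * self.lambda_ + 1.0, 1.0 / self.lambda_)
        return x - self.shift


@dataclass
class TransformModel:
    """Per-variable transform parameters for a table."""

    variables: dict[str, VariableTransform] = field(default_factory=dict)

    def __getitem__(self, name: str) -> VariableTransform:
        return self.variables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.variables


def _normality_criterion(y: np.ndarray) -> float:
    """Larger is more Gaussian.  Shapiro-Wilk W for small n; for n > 50 the
    negated Anderson-Darling A2 (finer-grained in the tails)."""
    if y.size <= 50:
        return float(stats.shapiro(y).statistic)
    return -float(stats.anderson(y, dist="norm", method="interpolate").statistic)


def fit_power_transform(
    values: Iterable[float],
    grid: np.ndarray | None = None,
    shift: float = 0.0,
) -> VariableTransform:
    """Choose the Box-Cox exponent maximizing the normality criterion.

    Raises for fewer than 8 finite values, constant input, or non-positive
    values when no adequate shift is supplied.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    x = x[np.isfinite(x)]
    if x.size < _MIN_N:
        raise ValueError(f"need at least {_MIN_N} finite values, got {x.size}")
    if np.min(x) + shift <= 0:
        raise ValueError(
            "non-positive values: supply a shift making all values positive"
        )
    if np.ptp(x) == 0:
        raise ValueError("constant input has no defined power transform")
    xs = x + shift
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    log_xs = np.log(xs)
    best_lambda = np.nan
    best_score = -np.inf
    for lam in grid:
        y = log_xs if lam == 0.0 else (np.power(xs, lam) - 1.0) / lam
        if not np.all(np.isfinite(y)) or np.ptp(y) == 0:
            continue
        score = _normality_criterion(y)
        if score > best_score:
            best_score = score
            best_lambda = float(lam)
    if not np.isfinite(best_lambda):
        raise ValueError("no grid point produced a finite transform")
    y = log_xs if best_lambda == 0.0 else (np.power(xs, best_lambda) - 1.0) / best_lambda
    sd = float(np.std(y, ddof=1))
    if sd <= 0:
        raise ValueError("transformed variable is constant")
    return VariableTransform(
        lambda_=best_lambda,
        shift=shift,
        mean=float(np.mean(y)),
        sd=sd,
        criterion=best_score,
    )


def fit_table(
    table: pd.DataFrame,
    grid: np.ndarray | None = None,
    shifts: Mapping[str, float] | None = None,
) -> TransformModel:
    """Fit a transform per column (pooled over all samples).

    Columns that cannot be fitted (too few values, constant) are skipped --
    downstream screens then simply do not see them.
    """
    model = TransformModel()
    for col in table.columns:
        shift = (shifts or {}).get(col, 0.0)
        try:
            model.variables[col] = fit_power_transform(
                table[col].to_numpy(dtype=float), grid=grid, shift=shift
            )
        except ValueError:
            continue
    return model


def apply_transform(
    model: TransformModel, table: pd.DataFrame, standardize: bool = True
) -> pd.DataFrame:
    """Transform every column of ``table`` with its fitted parameters."""
    missing = [c for c in table.columns if c not in model]
    if missing:
        raise KeyError(f"variables absent from transform model: {missing}")
    out = {}
    for col in table.columns:
        out[col] = model[col].forward(table[col].to_numpy(dtype=float), standardize)
    return pd.DataFrame(out, index=table.index)


def inverse_transform(
    model: TransformModel, table: pd.DataFrame, standardized: bool = True
) -> pd.DataFrame:
    out = {}
    for col in table.columns:
        out[col] = model[col].inverse(table[col].to_numpy(dtype=float), standardized)
    return pd.DataFrame(out, index=table.index)
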