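"""Univariate screening: two-factor ANOVA, descriptives, severity correlations.

Each (transformed) variable is screened with a main-effects ANOVA with the
factors disease status (patient vs control) and dichotomized age (<= 38 vs
> 38 years), the age cut absorbing the age dependence of many steroids.
The status effect is summarised by partial eta-squared and its p-value, plus
a direction code (up/down in patients) whose sign feeds the trend
meta-statistic.  Severity indices (EDSS, T25FWT, 9-hole peg test right/left)
are correlated with each variable within patients only, since controls carry
no severity scores.

No multiplicity correction is applied to the per-variable p-values: the
trend meta-test over each panel's direction codes is the aggregate answer to
multiplicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .trend import TrendCounts

__all__ = [
    "AGE_CUT",
    "ScreenResult",
    "anova_ms_age",
    "describe_groups",
    "correlate_severity",
    "screen_table",
    "code_directions",
]

AGE_CUT = 38.0  # years; <= 38 vs > 38


@dataclass
class ScreenResult:
    """Univariate screen outcome for one variable."""

    variable: str
    eta_p_sq: float
    p_ms: float
    direction: str  # "up" | "down": patients vs controls on the transformed scale
    group_summary: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    correlations: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_ms < 0.05


def anova_ms_age(
    values: Iterable[float],
    group: Iterable[str],
    age: Iterable[float],
) -> tuple[float, float, str]:
    """Main-effects ANOVA of a transformed variable on status and age group.

    Age is dichotomized at 38 years; the status sum of squares is the
    Type-III (drop-one) SS given the age factor, so the decomposition is
    valid for unbalanced designs.  Returns (partial eta-squared, p for the
    status factor, direction of the status effect).

    If one age level is empty after dichotomization the model degrades to a
    one-way ANOVA on status, with a warning.
    """
    y = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    g = np.asarray(list(group))
    a = np.asarray(list(age) if not isinstance(age, np.ndarray) else age, dtype=float)
    keep = np.isfinite(y) & np.isfinite(a)
    y, g, a = y[keep], g[keep], a[keep]
    ms = (g == "patient").astype(float)
    if ms.sum() == 0 or ms.sum() == ms.size:
        raise ValueError("both patient and control groups must be non-empty")
    old = (a > AGE_CUT).astype(float)
    use_age = 0 < old.sum() < old.size
    if not use_age:
        warnings.warn(
            "one age level empty after dichotomization; falling back to "
            "one-way ANOVA on status",
            RuntimeWarning,
            stacklevel=2,
        )
    cols = [np.ones_like(y), ms] + ([old] if use_age else [])
    full = sm.OLS(y, np.column_stack(cols)).fit()
    reduced = sm.OLS(
        y, np.column_stack([np.ones_like(y)] + ([old] if use_age else []))
    ).fit()
    ss_ms = float(reduced.ssr - full.ssr)
    ss_res = float(full.ssr)
    df_res = int(full.df_resid)
    if ss_res <= 0 or df_res <= 0:
        # saturated / exact fit: effect explains everything
        return (1.0 if ss_ms > 0 else 0.0), (0.0 if ss_ms > 0 else 1.0), _dir(full)
    f_stat = (ss_ms / 1.0) / (ss_res / df_res)
    p = float(stats.f.sf(f_stat, 1, df_res))
    eta_p = ss_ms / (ss_ms + ss_res)
    return float(eta_p), p, _dir(full)


def _dir(fitted) -> str:
    return "up" if fitted.params[1] >= 0 else "down"


def describe_groups(
    values: Iterable[float], group: Iterable[str]
) -> dict[str, tuple[float, float, float]]:
    """Median (25th, 75th percentile) per group on the original scale,
    with the linear-interpolation quantile convention."""
    y = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    g = np.asarray(list(group))
    out: dict[str, tuple[float, float, float]] = {}
    for label in ("control", "patient"):
        vals = y[(g == label) & np.isfinite(y)]
        if vals.size < 3:
            raise ValueError(f"group {label!r} absent or too small to summarise")
        med, q1, q3 = np.percentile(vals, [50, 25, 75], method="linear")
        out[label] = (float(med), float(q1), float(q3))
    return out


def correlate_severity(
    values: Iterable[float],
    indices: pd.DataFrame,
    method: str = "pearson",
    min_pairs: int = 5,
) -> dict[str, tuple[float, float]]:
    """Correlate one transformed variable with each severity index.

    Expects patient-only rows.  Pearson (with the two-sided t test on n-2
    degrees of freedom) by default; Spearman behind the flag.  Indices with
    fewer than ``min_pairs`` complete pairs yield (nan, nan).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    y = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    out: dict[str, tuple[float, float]] = {}
    for col in indices.columns:
        x = indices[col].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        if keep.sum() < min_pairs:
            out[col] = (float("nan"), float("nan"))
            continue
        if np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
            out[col] = (float("nan"), float("nan"))
            continue
        if method == "pearson":
            r, p = stats.pearsonr(x[keep], y[keep])
        else:
            r, p = stats.spearmanr(x[keep], y[keep])
        out[col] = (float(r), float(p))
    return out


def screen_table(
    transformed: pd.DataFrame,
    meta: pd.DataFrame,
    original: pd.DataFrame | None = None,
    severity: Sequence[str] = ("EDSS", "T25FWT", "HPT9_R", "HPT9_L"),
    method: str = "pearson",
) -> list[ScreenResult]:
    """Screen every column: ANOVA, group descriptives, severity correlations."""
    group = meta["group"].to_numpy()
    age = meta["age"].to_numpy(dtype=float)
    patients = group == "patient"
    sev_cols = [c for c in severity if c in meta.columns]
    sev = meta.loc[patients, sev_cols] if sev_cols else None
    results = []
    for col in transformed.columns:
        y = transformed[col].to_numpy(dtype=float)
        eta, p, direction = anova_ms_age(y, group, age)
        res = ScreenResult(variable=col, eta_p_sq=eta, p_ms=p, direction=direction)
        if original is not None and col in original.columns:
            try:
                res.group_summary = describe_groups(
                    original[col].to_numpy(dtype=float), group
                )
            except ValueError:
                pass
        if sev is not None:
            res.correlations = correlate_severity(y[patients], sev, method=method)
        results.append(res)
    return results


def code_directions(
    results: Iterable[ScreenResult],
    groups: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> dict[str, TrendCounts]:
    """Collapse screen results into (up / non-significant / down) triplets.

    ``groups`` maps a panel name to the variable names it contains; each
    triplet counts, within the panel, variables significant at ``alpha``
    with a positive direction, significant with a negative direction, and
    the non-significant remainder, so the components always sum to the
    panel size.
    """
    by_name = {r.variable: r for r in results}
    out: dict[str, TrendCounts] = {}
    for name, members in groups.items():
        u = m = d = 0
        for var in members:
            r = by_name.get(var)
            if r is None:
                raise KeyError(f"group {name!r} references unscreened variable {var!r}")
            if r.p_ms < alpha:
                if r.direction == "up":
                    u += 1
                else:
                    d += 1
            else:
                m += 1
        out[name] = TrendCounts(u, m, d)
    return out


def code_correlation_directions(
    results: Iterable[ScreenResult],
    groups: Mapping[str, Sequence[str]],
    index: str,
    alpha: float = 0.05,
) -> dict[str, TrendCounts]:
    """Direction triplets for severity-index correlations instead of the
    status effect: significant positive / non-significant / significant
    negative correlations with ``index`` within each panel."""
    by_name = {r.variable: r for r in results}
    out: dict[str, TrendCounts] = {}
    for name, members in groups.items():
        u = m = d = 0
        for var in members:
            r = by_name.get(var)
            if r is None:
                raise KeyError(f"group {name!r} references unscreened variable {var!r}")
            rv, pv = r.correlations.get(index, (float("nan"), float("nan")))
            if np.isfinite(pv) and pv < alpha:
                if rv > 0:
                    u += 1
                else:
                    d += 1
            else:
                m += 1
        out[name] = TrendCounts(u, m, d)
    return out
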