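"""End-to-end pipeline: transform -> ratios -> screen -> trends -> OPLS.

Mirrors the study's analysis sequence: power-transform every metric
variable, evaluate the enzyme-panel molar ratios, screen each variable with
the status x age ANOVA (and severity correlations in patients), collapse
each panel's significance directions into a trend triplet and test it, then
fit a per-panel OPLS classifier with homogeneity screening, VIP pruning and
cross-validated explained variability.  Results are written as CSV tables
plus a text report that echoes the "(u/m/d, p = ...)" notation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import opls as opls_mod
from .catalog import (
    SEVERITY_INDICES,
    ConcentrationTable,
    SteroidCatalog,
    default_catalog,
    evaluate_ratios,
    load_catalog,
)
from .screen import ScreenResult, code_directions, screen_table
from .transform import apply_transform, fit_table
from .trend import TrendResult, trend_test

__all__ = ["PipelineConfig", "run_pipeline", "format_trend"]

log = logging.getLogger("steroidomics")


@dataclass
class PipelineConfig:
    """Serializable run configuration; defaults reproduce the study setup."""

    input_csv: str | None = None
    catalog_path: str | None = None
    out_dir: str | None = None
    alpha: float = 0.05
    lambda_min: float = -3.0
    lambda_max: float = 3.0
    lambda_step: float = 0.01
    correlation_method: str = "pearson"
    vip_threshold: float = 1.0
    cv_folds: int = 7
    hotelling_level: float = 0.95
    seed: int = 0
    panels: list[str] = field(default_factory=list)  # empty -> all

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.lambda_step <= 0 or self.lambda_min >= self.lambda_max:
            raise ValueError("invalid transform grid")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.hotelling_level <= 1:
            raise ValueError("hotelling_level must be in (0, 1]")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("correlation_method must be pearson or spearman")

    @property
    def grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.lambda_min, self.lambda_max + 1e-9, self.lambda_step), 10
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def format_trend(counts, result: TrendResult) -> str:
    """Report line in the conventional notation, e.g. "(5/61/15, p = 0.026)"."""
    p = result.p_two_sided
    if p < 0.0005:
        return f"({counts.n_up}/{counts.n_null}/{counts.n_down}, p < 0.001)"
    return f"({counts.n_up}/{counts.n_null}/{counts.n_down}, p = {p:.3f})"


def _variable_groups(catalog: SteroidCatalog, ratio_cols: list[str]) -> dict:
    """Panels of variables whose direction codes are aggregated."""
    groups: dict[str, list[str]] = {
        "total steroids": list(catalog.analytes),
        "unconjugated steroids": catalog.unconjugated,
        "conjugated steroids": catalog.conjugated,
        "corticoids + 11b-OH-androstanes": catalog.by_class("corticoid")
        + catalog.by_class("11b-hydroxy-androstane"),
        "delta5 + delta4 steroids": catalog.by_class("delta5")
        + catalog.by_class("delta4"),
        "5a-reduced steroids": catalog.by_class("5a-reduced"),
        "5b-reduced steroids": catalog.by_class("5b-reduced"),
    }
    for panel in catalog.panel_names():
        cols = [c for c in ratio_cols if c.startswith(panel + ":")]
        groups[f"ratios {panel}"] = cols
    sub = [
        f"{r.panel}:{r.name}"
        for r in catalog.ratios
        if r.subgroup == "7ab-OH-D5" and f"{r.panel}:{r.name}" in ratio_cols
    ]
    if sub:
        groups["ratios 7a/b-OH of delta5 androgens"] = sub
    return groups


def _fit_panel_opls(X: pd.DataFrame, y: np.ndarray, config: PipelineConfig) -> dict:
    """Homogeneity screen, VIP pruning, CV and classification for one panel."""
    keep_rows = np.ones(len(y), dtype=bool)
    model = opls_mod.fit_opls(X, y)
    for _ in range(2):  # at most two outlier-removal rounds
        inliers = opls_mod.hotelling_screen(model, level=config.hotelling_level)
        if inliers.all():
            break
        idx = np.where(keep_rows)[0][~inliers]
        keep_rows[idx] = False
        model = opls_mod.fit_opls(X[keep_rows], y[keep_rows])
    model, kept_vars = opls_mod.select_predictors(model, threshold=config.vip_threshold)
    Xk = X.loc[keep_rows, list(kept_vars)]
    yk = y[keep_rows]
    explained_cv = opls_mod.cross_validated_explained(Xk, yk, folds=config.cv_folds)
    model.explained_cv = explained_cv
    report = opls_mod.classification_report(model, Xk, yk)
    return {
        "model": model,
        "report": report,
        "variables": kept_vars,
        "rows_kept": keep_rows,
        "summary": opls_mod.model_summary(model, folds=config.cv_folds),
    }


def run_pipeline(
    config: PipelineConfig, table: ConcentrationTable | None = None
) -> dict:
    """Run the full analysis; returns the result bundle and optionally
    writes it to ``config.out_dir``.

    Raises at the first failing stage with the stage name in the log.
    """
    stage = "load"
    try:
        catalog = (
            load_catalog(config.catalog_path) if config.catalog_path else default_catalog()
        )
        if table is None:
            if config.input_csv is None:
                raise ValueError("no input table: set input_csv or pass a table")
            table = ConcentrationTable.from_csv(config.input_csv)
        log.info("loaded %d samples x %d analytes", table.n_samples, table.data.shape[1])

        stage = "ratios"
        ratios = evaluate_ratios(catalog, table, panel="all")

        stage = "transform"
        metrics = pd.concat([table.in_nm(), ratios], axis=1)
        tmodel = fit_table(metrics, grid=config.grid)
        transformed = apply_transform(
            tmodel, metrics[[c for c in metrics.columns if c in tmodel]]
        )

        stage = "screen"
        have_severity = all(c in table.meta.columns for c in SEVERITY_INDICES) and (
            table.meta.loc[table.meta["group"] == "patient", list(SEVERITY_INDICES)]
            .notna()
            .any()
            .any()
        )
        if not have_severity:
            log.warning("severity indices absent; correlation stages skipped")
        results = screen_table(
            transformed,
            table.meta,
            original=metrics,
            severity=SEVERITY_INDICES if have_severity else (),
            method=config.correlation_method,
        )

        stage = "trend"
        groups = _variable_groups(catalog, list(ratios.columns))
        screened = {r.variable for r in results}
        groups = {
            name: [v for v in members if v in screened]
            for name, members in groups.items()
        }
        groups = {k: v for k, v in groups.items() if v}
        counts = code_directions(results, groups, alpha=config.alpha)
        trends = {name: trend_test(c) for name, c in counts.items()}

        stage = "opls"
        y = np.where(table.meta["group"].to_numpy() == "patient", 1.0, -1.0)
        opls_results: dict[str, dict] = {}
        panel_list = config.panels or catalog.panel_names()
        blocks: dict[str, list[str]] = {"steroids": [
            c for c in catalog.analytes if c in transformed.columns
        ]}
        for panel in panel_list:
            blocks[panel] = [
                c for c in ratios.columns
                if c.startswith(panel + ":") and c in transformed.columns
            ]
        for name, cols in blocks.items():
            X = transformed[cols].dropna(axis=1)
            complete = X.notna().all(axis=1).to_numpy()
            if X.shape[1] == 0:
                log.warning("panel %s: no usable variables; skipped", name)
                continue
            try:
                opls_results[name] = _fit_panel_opls(
                    X[complete].reset_index(drop=True), y[complete], config
                )
            except ValueError as exc:
                log.warning("panel %s: OPLS skipped (%s)", name, exc)
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise

    bundle = {
        "config": config,
        "catalog": catalog,
        "table": table,
        "ratios": ratios,
        "transform": tmodel,
        "transformed": transformed,
        "screen": results,
        "trend_counts": counts,
        "trends": trends,
        "opls": opls_results,
    }
    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _screen_frame(results: list[ScreenResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "variable": r.variable,
            "eta_p_sq": r.eta_p_sq,
            "p_MS": r.p_ms,
            "direction": r.direction,
        }
        for grp, (med, q1, q3) in r.group_summary.items():
            row[f"{grp}_median"] = med
            row[f"{grp}_q1"] = q1
            row[f"{grp}_q3"] = q3
        for idx, (rv, pv) in r.correlations.items():
            row[f"r_{idx}"] = rv
            row[f"p_{idx}"] = pv
        rows.append(row)
    return pd.DataFrame(rows)


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _screen_frame(bundle["screen"]).to_csv(out_dir / "screen.csv", index=False)
    bundle["ratios"].to_csv(out_dir / "ratios.csv", index=False)
    lines = ["Trend tests (up/non-significant/down, two-sided signed-rank p)", ""]
    for name, counts in bundle["trend_counts"].items():
        lines.append(f"{name}: {format_trend(counts, bundle['trends'][name])}")
    lines.append("")
    lines.append("OPLS panels")
    for name, res in bundle["opls"].items():
        model = res["model"]
        rep = res["report"]
        res["summary"].to_csv(
            out_dir / f"opls_{name.replace(':', '_').replace('/', '_')}.csv",
            index=False,
        )
        rep.to_frame().to_csv(
            out_dir / f"subjects_{name.replace(':', '_').replace('/', '_')}.csv",
            index=False,
        )
        lines.append(
            f"{name}: explained variability = {model.explained_fit:.1f}% "
            f"({model.explained_cv:.1f}% after cross-validation), "
            f"sensitivity = {rep.sensitivity:.3g} "
            f"({rep.sensitivity_ci[0]:.3g}-{rep.sensitivity_ci[1]:.3g}), "
            f"specificity = {rep.specificity:.3g} "
            f"({rep.specificity_ci[0]:.3g}-{rep.specificity_ci[1]:.3g}), "
            f"n = {rep.n_cases}+{rep.n_controls}, "
            f"{len(res['variables'])} predictors"
        )
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
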