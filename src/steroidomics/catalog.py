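"""Analyte catalog and enzyme-panel molar-ratio registry.

The steroidome panel measured by GC-MS/MS (plus estradiol by immunoassay)
comprises 81 analytes: 46 unconjugated steroids and 35 polar conjugates
(mostly sulfates).  Product/precursor molar ratios over this panel act as
nominal proxies for the activity of the interconverting enzymes
(e.g. 17-OH-Preg/Preg for the CYP17A1 hydroxylase step, F/E for HSD11B1,
conjugate/free pairs for the SULT2A1 vs STS balance).

The registry is a packaged declarative text file, not code, so that panel
membership stays auditable.  Concentrations are reported in mixed molar
units (pM / nM / uM); every ratio is evaluated after conversion to a common
nM scale, which makes it dimensionless and invariant to the unit each
analyte happens to be declared in.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Analyte",
    "RatioDef",
    "SteroidCatalog",
    "ConcentrationTable",
    "CatalogError",
    "load_catalog",
    "default_catalog",
    "to_molar",
    "evaluate_ratios",
    "MOLAR_UNITS",
    "STEROID_CLASSES",
    "PANELS",
]

#: conversion factors to the common nM scale
MOLAR_UNITS: Mapping[str, float] = {"pM": 1e-3, "nM": 1.0, "uM": 1e3}

STEROID_CLASSES = (
    "delta5",
    "delta4",
    "5a-reduced",
    "5b-reduced",
    "corticoid",
    "11b-hydroxy-androstane",
    "estrogen",
)

#: enzyme-panel identifiers, in registry order
PANELS = (
    "SULT2A1_vs_STS",
    "CYP17A1_hl",
    "CYP17A1_h",
    "CYP17A1_l",
    "HSD3B",
    "CYP11B1",
    "HSD11B1",
    "CYP7B1_3A4_3A7",
    "SRD5A",
    "AKR1D1",
    "AKR1C1_vs_HSD17B2",
    "AKR1C2_vs_HSD17B2_6_3a3b",
    "AKR1C2_vs_HSD17B2_6_3aoxo",
    "AKR1C3_vs_HSD17B2",
    "CYP19A1",
)

#: metadata columns expected ahead of the analyte block in concentration CSVs
META_COLUMNS = ("subject_id", "group", "age", "EDSS", "T25FWT", "HPT9_R", "HPT9_L")
SEVERITY_INDICES = ("EDSS", "T25FWT", "HPT9_R", "HPT9_L")


class CatalogError(ValueError):
    """Raised when a registry file violates referential integrity."""


@dataclass(frozen=True)
class Analyte:
    abbreviation: str
    full_name: str
    unit: str
    conjugated: bool
    parent: str | None = None  # unconjugated counterpart, if measured
    steroid_class: str = "delta5"
    note: str | None = None


@dataclass(frozen=True)
class RatioDef:
    """A named molar ratio: sum(numerator) / sum(denominator), dimensionless."""

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    panel: str
    display_scale: float = 1.0
    note: str | None = None

    @property
    def subgroup(self) -> str | None:
        if self.note and "subgroup:" in self.note:
            return self.note.split("subgroup:", 1)[1].split()[0]
        return None


@dataclass
class SteroidCatalog:
    analytes: dict[str, Analyte] = field(default_factory=dict)
    ratios: list[RatioDef] = field(default_factory=list)

    # -- queries ---------------------------------------------------------
    @property
    def unconjugated(self) -> list[str]:
        return [k for k, a in self.analytes.items() if not a.conjugated]

    @property
    def conjugated(self) -> list[str]:
        return [k for k, a in self.analytes.items() if a.conjugated]

    def panel(self, name: str) -> list[RatioDef]:
        out = [r for r in self.ratios if r.panel == name]
        if not out:
            raise KeyError(f"unknown panel {name!r}")
        return out

    def panel_names(self) -> list[str]:
        seen: list[str] = []
        for r in self.ratios:
            if r.panel not in seen:
                seen.append(r.panel)
        return seen

    def by_class(self, steroid_class: str) -> list[str]:
        if steroid_class not in STEROID_CLASSES:
            raise KeyError(f"unknown steroid class {steroid_class!r}")
        return [k for k, a in self.analytes.items() if a.steroid_class == steroid_class]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for key, a in self.analytes.items():
            if a.unit not in MOLAR_UNITS:
                raise CatalogError(f"analyte {key!r}: unknown unit {a.unit!r}")
            if a.steroid_class not in STEROID_CLASSES:
                raise CatalogError(
                    f"analyte {key!r}: unknown steroid class {a.steroid_class!r}"
                )
            if a.conjugated and a.parent is not None:
                parent = self.analytes.get(a.parent)
                if parent is None:
                    raise CatalogError(
                        f"analyte {key!r}: dangling parent {a.parent!r}"
                    )
                if parent.conjugated:
                    raise CatalogError(
                        f"analyte {key!r}: parent {a.parent!r} is itself conjugated"
                    )
            if a.conjugated and a.parent is None and not a.note:
                raise CatalogError(
                    f"analyte {key!r}: conjugate without parent needs a reason note"
                )
            if not a.conjugated and a.parent is not None:
                raise CatalogError(f"analyte {key!r}: unconjugated with a parent")
        seen: set[tuple[str, str]] = set()
        for r in self.ratios:
            if (r.panel, r.name) in seen:
                raise CatalogError(f"duplicate ratio {r.name!r} in panel {r.panel!r}")
            seen.add((r.panel, r.name))
            if not r.numerator or not r.denominator:
                raise CatalogError(f"ratio {r.name!r}: empty numerator or denominator")
            if set(r.numerator) & set(r.denominator):
                raise CatalogError(
                    f"ratio {r.name!r}: numerator and denominator overlap"
                )
            for key in (*r.numerator, *r.denominator):
                if key not in self.analytes:
                    raise CatalogError(f"ratio {r.name!r}: unknown analyte {key!r}")

    # -- serialisation ---------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = ["[analytes]"]
        for a in self.analytes.values():
            lines.append(
                "\t".join(
                    [
                        a.abbreviation,
                        a.full_name,
                        a.unit,
                        "1" if a.conjugated else "0",
                        a.parent or "-",
                        a.steroid_class,
                        a.note or "-",
                    ]
                )
            )
        lines.append("[ratios]")
        for r in self.ratios:
            lines.append(
                "\t".join(
                    [
                        r.panel,
                        r.name,
                        "+".join(r.numerator),
                        "+".join(r.denominator),
                        repr(r.display_scale),
                        r.note or "-",
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_catalog(text: str) -> SteroidCatalog:
    catalog = SteroidCatalog()
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.strip() in ("[analytes]", "[ratios]"):
            section = line.strip()[1:-1]
            continue
        fields = line.split("\t")
        if section == "analytes":
            if len(fields) != 7:
                raise CatalogError(f"line {lineno}: expected 7 analyte fields")
            key, name, unit, conj, parent, cls, note = fields
            if key in catalog.analytes:
                raise CatalogError(f"duplicate analyte key {key!r}")
            catalog.analytes[key] = Analyte(
                abbreviation=key,
                full_name=name,
                unit=unit,
                conjugated=conj == "1",
                parent=None if parent == "-" else parent,
                steroid_class=cls,
                note=None if note == "-" else note,
            )
        elif section == "ratios":
            if len(fields) != 6:
                raise CatalogError(f"line {lineno}: expected 6 ratio fields")
            panel, name, num, den, scale, note = fields
            catalog.ratios.append(
                RatioDef(
                    name=name,
                    numerator=tuple(num.split("+")),
                    denominator=tuple(den.split("+")),
                    panel=panel,
                    display_scale=float(scale),
                    note=None if note == "-" else note,
                )
            )
        else:
            raise CatalogError(f"line {lineno}: content outside a section")
    catalog.validate()
    return catalog


def load_catalog(path: str | Path | None = None) -> SteroidCatalog:
    """Load and validate a registry file; ``None`` loads the packaged default."""
    if path is None:
        text = (
            resources.files("steroidomics.data")
            .joinpath("steroid_catalog.tsv")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return _parse_catalog(text)


_DEFAULT: SteroidCatalog | None = None


def default_catalog() -> SteroidCatalog:
    """The packaged 81-analyte catalog (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_catalog(None)
    return _DEFAULT


def to_molar(value, unit: str):
    """Convert a concentration from its declared molar unit to nM.

    Accepts scalars or arrays; NaN passes through (missing measurement),
    negative concentrations are rejected.
    """
    if unit not in MOLAR_UNITS:
        raise CatalogError(f"unknown unit {unit!r}")
    arr = np.asarray(value, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("concentrations must be non-negative")
    out = arr * MOLAR_UNITS[unit]
    return float(out) if np.isscalar(value) else out


# ---------------------------------------------------------------------------
# concentration tables


@dataclass
class ConcentrationTable:
    """Samples x analytes of molar concentrations plus subject metadata.

    ``data`` holds concentrations in each analyte's declared unit
    (``units`` maps analyte -> unit); ``meta`` holds subject_id, group
    (patient/control), age and the severity indices where available.
    """

    data: pd.DataFrame
    units: dict[str, str]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.units]
        if missing:
            raise ValueError(f"no unit declared for analytes: {missing}")
        for col, unit in self.units.items():
            if unit not in MOLAR_UNITS:
                raise CatalogError(f"analyte {col!r}: unknown unit {unit!r}")
        if "group" in self.meta.columns:
            bad = set(self.meta["group"].dropna()) - {"patient", "control"}
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def in_nm(self) -> pd.DataFrame:
        """All concentrations on the common nM scale."""
        out = self.data.astype(float).copy()
        for col in out.columns:
            out[col] = out[col] * MOLAR_UNITS[self.units[col]]
        return out

    # -- CSV round trip: header suffix "name [unit]" declares each unit ---
    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        meta = self.meta.copy()
        data = self.data.copy()
        data.columns = [f"{c} [{self.units[c]}]" for c in data.columns]
        pd.concat([meta.reset_index(drop=True), data.reset_index(drop=True)], axis=1).to_csv(
            path, index=False, float_format="%.10g"
        )

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "ConcentrationTable":
        raw = pd.read_csv(path)
        meta_cols = [c for c in raw.columns if c in META_COLUMNS]
        units: dict[str, str] = {}
        data_cols: dict[str, str] = {}
        for c in raw.columns:
            if c in meta_cols:
                continue
            if c.endswith("]") and "[" in c:
                name, unit = c[:-1].rsplit(" [", 1)
            else:
                name, unit = c, "nM"  # bare columns default to nM
            units[name] = unit
            data_cols[c] = name
        data = raw[list(data_cols)].rename(columns=data_cols)
        return cls(data=data, units=units, meta=raw[meta_cols])


def evaluate_ratios(
    catalog: SteroidCatalog,
    table: ConcentrationTable,
    panel: str | Sequence[str] = "all",
) -> pd.DataFrame:
    """Per-sample molar ratios for one panel or all panels.

    Each ratio is sum(numerator in nM) / sum(denominator in nM), computed per
    subject (never from group summaries).  A missing constituent or a zero
    denominator yields a missing ratio value (with a warning for zeros); no
    imputation is performed.  Column names are ``"panel:name"`` so that the
    same printed ratio name may appear in two enzyme panels.
    """
    if panel == "all":
        defs = list(catalog.ratios)
    elif isinstance(panel, str):
        defs = catalog.panel(panel)
    else:
        defs = [r for p in panel for r in catalog.panel(p)]
    nm = table.in_nm()
    missing = {
        key
        for r in defs
        for key in (*r.numerator, *r.denominator)
        if key not in nm.columns
    }
    if missing:
        raise KeyError(f"table lacks analytes required by the panel: {sorted(missing)}")
    out = {}
    n_zero = 0
    for r in defs:
        num = nm[list(r.numerator)].sum(axis=1, skipna=False)
        den = nm[list(r.denominator)].sum(axis=1, skipna=False)
        zero = den == 0
        n_zero += int(zero.sum())
        den = den.mask(zero)
        out[f"{r.panel}:{r.name}"] = num / den
    if n_zero:
        warnings.warn(
            f"{n_zero} ratio value(s) undefined (zero denominator); set to missing",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(out, index=table.data.index)
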