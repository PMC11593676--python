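"""Synthetic steroidome case-control datasets with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* positive, right-skewed concentrations (log-normal marginals whose
  magnitudes track each analyte's declared unit: pM analytes sit around
  ~150 pM, nM around ~5 nM, uM around ~1 uM);
* correlated pathway blocks -- analytes of the same steroid class share a
  latent factor giving a within-block log-scale correlation rho;
* age dependence for a subset of analytes (log-linear in age);
* conjugated analytes coupled to their unconjugated parent (conjugate =
  parent x typical conjugation ratio x exp(noise)), so conjugate/free
  ratio panels carry realistic structure;
* plantable group effects: a chosen number of analytes shifted up or down
  in patients by a multiple of the log-scale spread (the default mimics a
  cohort where a handful of conjugates rise and ~15 free steroids fall);
* severity indices (EDSS, timed 25-foot walk, 9-hole peg tests) generated
  for patients only from one latent severity, optionally leaking into
  selected analytes so severity-correlation screens have signal to find.

The default sample sizes follow the study design the pipeline targets:
25 female patients and 15 age-matched controls, ages ~39 (32, 49) years.
Everything is driven by one integer seed; the same seed reproduces the
dataset byte-for-byte through CSV round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog import MOLAR_UNITS, ConcentrationTable, SteroidCatalog, default_catalog

__all__ = ["SimulationDesign", "simulate"]

# typical baseline medians per declared unit, on that unit's own scale
_BASE_MEDIAN = {"pM": 150.0, "nM": 5.0, "uM": 1.0}
_CONJ_RATIO_NM = 50.0  # typical conjugate/free molar ratio


@dataclass
class SimulationDesign:
    """Parameters of one synthetic case-control steroidome."""

    n_patients: int = 25
    n_controls: int = 15
    #: log-age distribution: median ~39 y, quartiles ~32-49 y
    age_log_median: float = np.log(38.5)
    age_log_sd: float = 0.30
    catalog: SteroidCatalog | None = None
    sd_log: float = 0.6            # log-scale spread per analyte (IQR ratio ~2.2)
    block_rho: float = 0.5         # within-pathway-block log correlation
    n_up: int = 5                  # analytes shifted up in patients (conjugates)
    n_down: int = 15               # analytes shifted down in patients (free steroids)
    effect_size: float = 1.0       # group shift in units of sd_log
    effects: Mapping[str, float] | None = None  # explicit per-analyte shifts (sd units)
    age_fraction: float = 0.5      # share of analytes with an age slope
    age_slope_sd: float = 0.15     # log-units per decade, sign alternating
    coupling_sd: float = 0.3       # conjugate-vs-parent log noise
    severity_gamma: float = 0.4    # latent-severity leak into coupled analytes
    n_severity_coupled: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_controls) < 3:
            raise ValueError("need at least 3 subjects per group")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if self.sd_log <= 0 or self.coupling_sd < 0:
            raise ValueError("spreads must be positive")


def _draw_effects(design: SimulationDesign, catalog: SteroidCatalog, rng) -> dict:
    if design.effects is not None:
        unknown = set(design.effects) - set(catalog.analytes)
        if unknown:
            raise KeyError(f"effects reference unknown analytes: {sorted(unknown)}")
        return dict(design.effects)
    effects: dict[str, float] = {}
    conj = catalog.conjugated
    free = catalog.unconjugated
    if design.n_up > len(conj) or design.n_down > len(free):
        raise ValueError("more planted effects than candidate analytes")
    ups = rng.choice(len(conj), size=design.n_up, replace=False)
    downs = rng.choice(len(free), size=design.n_down, replace=False)
    for i in ups:
        effects[conj[i]] = design.effect_size
    for i in downs:
        effects[free[i]] = -design.effect_size
    return effects


def simulate(design: SimulationDesign) -> tuple[ConcentrationTable, dict]:
    """Generate one dataset plus its ground-truth record.

    Returns the concentration table (analytes in their declared units, with
    subject metadata) and a dict with the planted effect signs (both as
    planted and as effective after conjugate-parent coupling), the
    age-slope map, the severity-coupled analytes and the seed.
    """
    catalog = design.catalog or default_catalog()
    rng = np.random.default_rng(design.seed)
    n = design.n_patients + design.n_controls
    is_patient = np.zeros(n, dtype=bool)
    is_patient[: design.n_patients] = True

    age = np.exp(rng.normal(design.age_log_median, design.age_log_sd, size=n))
    age = np.clip(age, 18.0, 70.0)

    effects = _draw_effects(design, catalog, rng)
    keys = list(catalog.analytes)
    free_keys = catalog.unconjugated
    age_keys = [k for i, k in enumerate(keys) if i % int(round(1 / design.age_fraction)) == 0] \
        if design.age_fraction > 0 else []
    age_slopes = {
        k: design.age_slope_sd * (1 if i % 2 == 0 else -1)
        for i, k in enumerate(age_keys)
    }

    # latent severity (patients), centered so it does not shift group means
    sev = rng.normal(size=design.n_patients)
    sev = sev - sev.mean()
    down_keys = sorted(k for k, v in effects.items() if v < 0)
    severity_coupled = down_keys[: design.n_severity_coupled]

    classes = {k: catalog.analytes[k].steroid_class for k in keys}
    block_names = sorted(set(classes.values()))
    block_factor = {b: rng.normal(size=n) for b in block_names}

    log_nm: dict[str, np.ndarray] = {}
    rho = design.block_rho
    for k in free_keys:
        a = catalog.analytes[k]
        base = np.log(_BASE_MEDIAN[a.unit] * MOLAR_UNITS[a.unit])
        z = np.sqrt(rho) * block_factor[classes[k]] + np.sqrt(1 - rho) * rng.normal(size=n)
        vals = base + design.sd_log * z
        vals += age_slopes.get(k, 0.0) * (age - 39.0) / 10.0
        vals += effects.get(k, 0.0) * design.sd_log * is_patient
        if k in severity_coupled:
            vals[is_patient] += design.severity_gamma * design.sd_log * sev
        log_nm[k] = vals

    effective = {k: effects.get(k, 0.0) for k in keys}
    for k in catalog.conjugated:
        a = catalog.analytes[k]
        shift = effects.get(k, 0.0) * design.sd_log * is_patient
        noise = design.coupling_sd * rng.normal(size=n)
        if a.parent is not None:
            vals = log_nm[a.parent] + np.log(_CONJ_RATIO_NM) + noise + shift
            effective[k] = effects.get(k, 0.0) + effective[a.parent]
        else:
            base = np.log(_BASE_MEDIAN[a.unit] * MOLAR_UNITS[a.unit])
            z = np.sqrt(rho) * block_factor[classes[k]] + np.sqrt(1 - rho) * rng.normal(size=n)
            vals = base + design.sd_log * z + shift
            vals += age_slopes.get(k, 0.0) * (age - 39.0) / 10.0
        if k in severity_coupled:
            vals[is_patient] += design.severity_gamma * design.sd_log * sev
        log_nm[k] = vals

    data = pd.DataFrame(
        {
            k: np.exp(log_nm[k]) / MOLAR_UNITS[catalog.analytes[k].unit]
            for k in keys
        }
    )
    units = {k: catalog.analytes[k].unit for k in keys}

    edss = np.clip(np.round((2.5 + 1.2 * sev + 0.5 * rng.normal(size=design.n_patients)) * 2) / 2, 0, 7)
    t25 = np.exp(1.6 + 0.25 * sev + 0.10 * rng.normal(size=design.n_patients))
    hptr = np.exp(3.0 + 0.20 * sev + 0.08 * rng.normal(size=design.n_patients))
    hptl = np.exp(3.0 + 0.20 * sev + 0.08 * rng.normal(size=design.n_patients))

    meta = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "group": np.where(is_patient, "patient", "control"),
            "age": np.round(age, 1),
            "EDSS": np.concatenate([edss, np.full(design.n_controls, np.nan)]),
            "T25FWT": np.concatenate([np.round(t25, 2), np.full(design.n_controls, np.nan)]),
            "HPT9_R": np.concatenate([np.round(hptr, 2), np.full(design.n_controls, np.nan)]),
            "HPT9_L": np.concatenate([np.round(hptl, 2), np.full(design.n_controls, np.nan)]),
        }
    )

    table = ConcentrationTable(data=data, units=units, meta=meta)
    truth = {
        "seed": design.seed,
        "effects_planted": effects,
        "effects_effective": {k: v for k, v in effective.items() if v != 0.0},
        "age_slopes": age_slopes,
        "severity_coupled": list(severity_coupled),
        "latent_severity": sev,
    }
    return table, truth
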