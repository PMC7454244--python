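"""Virtual-patient generation: parameter space, LHS sampling, screening.

A cohort is drawn by Latin hypercube sampling over a declared parameter
space (each axis linear or log10-uniform), each draw is grown to its
pre-treatment tumor size, and physiological plausibility bounds on tumor
diameter, blood T-cell density, intratumoral activated-T density and the
Teff/Treg ratio decide which virtual patients enter the trial.
Implausible patients are retained in the cohort, flagged with their
exclusion reasons, so exclusion counts are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .model_core import (
    ModelParams, ModelState, initialize_pretreatment, pretreatment_observables,
)

__all__ = [
    "ParameterAxis", "ScreenBounds", "CohortPatient", "Cohort",
    "default_parameter_space", "default_screen_bounds", "DELTA_AXIS",
    "lhs_sample", "screen_patient", "generate_cohort", "with_delta_axis",
]


@dataclass(frozen=True)
class ParameterAxis:
    """One sampled axis of the virtual-patient parameter space."""

    name: str
    baseline: float
    low: float
    high: float
    scale: str = "linear"  # or "log10"
    unit: str = ""

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"scale must be linear or log10, got {self.scale!r}")
        if not self.low < self.high:
            raise ValueError(f"axis {self.name}: low must be < high")
        if not (self.low <= self.baseline <= self.high):
            raise ValueError(f"axis {self.name}: baseline outside [low, high]")
        if self.scale == "log10" and self.low <= 0:
            raise ValueError(f"axis {self.name}: log10 axis must be positive")

    def from_unit(self, u: np.ndarray | float) -> np.ndarray | float:
        """Map normalized [0, 1] coordinates to parameter values."""
        if self.scale == "log10":
            lo, hi = math.log10(self.low), math.log10(self.high)
            return 10.0 ** (lo + (hi - lo) * np.asarray(u, dtype=float))
        return self.low + (self.high - self.low) * np.asarray(u, dtype=float)

    def to_unit(self, x: np.ndarray | float) -> np.ndarray | float:
        """Normalize parameter values to [0, 1] under the sampling scale."""
        if self.scale == "log10":
            lo, hi = math.log10(self.low), math.log10(self.high)
            return (np.log10(np.asarray(x, dtype=float)) - lo) / (hi - lo)
        return (np.asarray(x, dtype=float) - self.low) / (self.high - self.low)


def default_parameter_space() -> list[ParameterAxis]:
    """Packaged parameter space for the MSS CRC virtual population.

    Receptor densities, affinities, TMB and pool sizes are log10 axes;
    rates bounded near zero and the dimensionless efficiencies are linear.
    The TMB range [1, 220] clones anchors the normalized coordinate 0.8
    at roughly 76 clones.  Ranges are calibration targets standing in for
    unavailable study-level tables (see docs/methods.md).
    """
    return [
        ParameterAxis("k_growth", 0.012, 0.004, 0.030, "linear", "1/day"),
        ParameterAxis("d_init", 3.0, 1.0, 8.0, "linear", "cm"),
        ParameterAxis("n_clones", 20.0, 1.0, 220.0, "log10", "clones"),
        ParameterAxis("pd1_total", 3.0e3, 1.0e3, 3.0e4, "log10", "sites/cell"),
        ParameterAxis("pdl1_cancer", 5.0e3, 3.0e2, 3.0e5, "log10", "sites/cell"),
        ParameterAxis("pdl1_apc", 1.0e4, 1.0e3, 1.0e5, "log10", "sites/cell"),
        ParameterAxis("chi", 1.0, 0.0, 10.0, "linear", ""),
        ParameterAxis("cea_total", 1.0e5, 1.0e3, 1.0e6, "log10", "sites/cell"),
        ParameterAxis("lam", 2.0, 0.0, 10.0, "linear", ""),
        ParameterAxis("cd3_total", 5.0e4, 1.0e4, 2.0e5, "log10", "sites/cell"),
        ParameterAxis("kd_cd3", 1.0e-7, 1.0e-8, 1.0e-6, "log10", "M"),
        ParameterAxis("kd_cea", 5.0e-9, 1.0e-9, 1.0e-7, "log10", "M"),
        ParameterAxis("r_pdl2", 0.035, 0.0, 0.07, "linear", ""),
        ParameterAxis("q_in", 0.5, 0.05, 5.0, "log10", "1/day"),
        ParameterAxis("naive_pool", 5.0e9, 2.0e9, 1.2e10, "log10", "cells"),
        ParameterAxis("treg_activity", 1.0, 0.1, 10.0, "log10", ""),
    ]


#: optional axis enabling the delta-weighted PD-L2 Hill variant
DELTA_AXIS = ParameterAxis("delta", 0.5, 0.0, 1.0, "linear", "")


@dataclass(frozen=True)
class ScreenBounds:
    """Plausibility bounds on pre-treatment observables.

    Defaults are clinically motivated placeholders standing in for
    study-level bounds: diameter [1, 15] cm, blood T density
    [400, 3200] /uL, intratumoral activated-T density [1e2, 1e7] /cm^3,
    Teff/Treg ratio [0.1, 50].
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "tumor_diameter_cm": (1.0, 15.0),
        "blood_t_density": (400.0, 3200.0),
        "tumor_activated_t_density": (1.0e2, 1.0e7),
        "teff_treg_ratio": (0.1, 50.0),
    })

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"screen bound {name}: low must be < high")


def default_screen_bounds() -> ScreenBounds:
    return ScreenBounds()


@dataclass
class CohortPatient:
    patient_id: int
    params: ModelParams
    sampled: dict[str, float]
    plausible: bool
    reasons: list[str]
    pre_state: ModelState | None
    observables: dict[str, float]


@dataclass
class Cohort:
    patients: list[CohortPatient]
    seed: int
    space: list[ParameterAxis]

    @property
    def plausible(self) -> list[CohortPatient]:
        return [p for p in self.patients if p.plausible]

    @property
    def n_plausible(self) -> int:
        return len(self.plausible)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {"patient_id": p.patient_id, **p.sampled,
                   "plausible": p.plausible,
                   "reasons": ";".join(p.reasons)}
            row.update({f"obs_{k}": v for k, v in p.observables.items()})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def lhs_sample(space: Sequence[ParameterAxis], n: int, seed: int) -> pd.DataFrame:
    """Latin hypercube sample of ``n`` virtual patients.

    Each axis is stratified into ``n`` equal-probability strata of its
    (linear or log10) range with exactly one uniformly jittered sample
    per stratum; stratum permutations are independent across axes given
    the seed.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(space), scramble=True, rng=np.random.default_rng(seed))
    unit = sampler.random(n)
    data = {ax.name: ax.from_unit(unit[:, j]) for j, ax in enumerate(space)}
    return pd.DataFrame(data)


def screen_patient(pre_state: ModelState, observables: dict[str, float],
                   bounds: ScreenBounds) -> tuple[bool, list[str]]:
    """Plausibility decision from the pre-treatment state and bounds.

    A patient is plausible iff a tumor developed and every screened
    observable lies within its bounds; the reason list names every
    violated bound in the stable order of ``bounds.bounds``.
    """
    reasons: list[str] = []
    if pre_state.no_tumor:
        reasons.append("no_tumor")
    else:
        for name, (lo, hi) in bounds.bounds.items():
            v = observables.get(name, math.nan)
            if not (lo <= v <= hi):
                reasons.append(name)
    return (not reasons), reasons


def with_delta_axis(cohort: Cohort, seed: int,
                    bounds: ScreenBounds | None = None) -> Cohort:
    """Re-derive a cohort with the PD-L2 Hill weight delta sampled as one
    additional LHS axis over the *same* patients.

    The original axes keep their sampled values (paired design), so the
    effect of weighting PD-L2 down is not confounded with cohort
    resampling; each patient is re-grown and re-screened under its delta.
    """
    bounds = bounds if bounds is not None else default_screen_bounds()
    deltas = lhs_sample([DELTA_AXIS], len(cohort.patients), seed)["delta"]
    patients = []
    for patient, delta in zip(cohort.patients, deltas):
        params = patient.params.with_updates(delta=float(delta))
        pre = initialize_pretreatment(params)
        obs = (pretreatment_observables(pre, params)
               if not pre.no_tumor else {})
        ok, reasons = screen_patient(pre, obs, bounds)
        patients.append(CohortPatient(
            patient_id=patient.patient_id, params=params,
            sampled={**patient.sampled, "delta": float(delta)},
            plausible=ok, reasons=reasons, pre_state=pre, observables=obs))
    return Cohort(patients=patients, seed=cohort.seed,
                  space=list(cohort.space) + [DELTA_AXIS])


def generate_cohort(space: Sequence[ParameterAxis] | None = None,
                    n: int = 2000, seed: int = 1,
                    bounds: ScreenBounds | None = None,
                    base_params: ModelParams | None = None) -> Cohort:
    """Sample, pre-grow and screen a virtual cohort (deterministic per seed)."""
    space = list(space) if space is not None else default_parameter_space()
    bounds = bounds if bounds is not None else default_screen_bounds()
    base = base_params if base_params is not None else ModelParams()
    table = lhs_sample(space, n, seed)
    patients = []
    for i, row in table.iterrows():
        sampled = {k: float(v) for k, v in row.items()}
        params = base.with_updates(**sampled)
        pre = initialize_pretreatment(params)
        obs = (pretreatment_observables(pre, params)
               if not pre.no_tumor else {})
        ok, reasons = screen_patient(pre, obs, bounds)
        patients.append(CohortPatient(
            patient_id=int(i), params=params, sampled=sampled,
            plausible=ok, reasons=reasons, pre_state=pre, observables=obs))
    return Cohort(patients=patients, seed=seed, space=space)
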