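"""Run configuration schema, manifest writing and the smoke fixture.

The trial is a many-parameter object, so a single YAML config (strictly
validated, unknown keys rejected) carries the parameter space, screening
bounds, arm specs, seeds and solver settings; CLI flags only override
config values.  Every run can write a manifest (config hash, seeds,
package version) sufficient to reproduce deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .model_core import ModelParams
from .pharmacokinetics import Regimen
from .trial_engine import ArmSpec, default_arms
from .virtual_cohort import (
    DELTA_AXIS, ParameterAxis, ScreenBounds, default_parameter_space,
    default_screen_bounds,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "make_smoke_fixture",
           "write_manifest"]


class ConfigError(ValueError):
    """Raised with every schema violation listed, not just the first."""


class AxisModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    baseline: float
    low: float
    high: float
    scale: Literal["linear", "log10"] = "linear"
    unit: str = ""


class BoundModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    low: float
    high: float


class RegimenModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    drug_id: Literal["atezolizumab", "cibisatamab"]
    dose_mg: float = Field(ge=0)
    interval_days: float = Field(gt=0)
    first_dose_day: float = Field(default=0.0, ge=0)
    n_doses: int | None = None


class ArmModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    arm_id: str
    regimens: list[RegimenModel]
    horizon_days: float = Field(default=400.0, gt=0)


class SolverModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rtol: float = Field(default=1e-6, gt=0)
    atol: float = Field(default=1e-3, gt=0)
    grid_step: float = Field(default=5.0, gt=0)


class RunConfig(BaseModel):
    """Validated run configuration with documented defaults."""

    model_config = ConfigDict(extra="forbid")

    cohort_size: int = Field(default=2000, ge=1)
    cohort_seed: int = 1
    bootstrap_seed: int = 20
    enable_delta_axis: bool = False
    parameter_space: list[AxisModel] | None = None
    screen_bounds: list[BoundModel] | None = None
    arms: list[ArmModel] | None = None
    model_overrides: dict[str, float] = Field(default_factory=dict)
    solver: SolverModel = Field(default_factory=SolverModel)
    output_dir: str = "results"

    @model_validator(mode="after")
    def _check_overrides(self) -> "RunConfig":
        valid = {f.name for f in ModelParams.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(self.model_overrides) - valid
        if unknown:
            raise ValueError(
                f"unknown model_overrides keys: {sorted(unknown)}")
        return self

    # -- converters to library objects -------------------------------------
    def space(self) -> list[ParameterAxis]:
        if self.parameter_space is None:
            axes = default_parameter_space()
        else:
            axes = [ParameterAxis(**a.model_dump()) for a in self.parameter_space]
        if self.enable_delta_axis and all(a.name != "delta" for a in axes):
            axes.append(DELTA_AXIS)
        return axes

    def bounds(self) -> ScreenBounds:
        if self.screen_bounds is None:
            return default_screen_bounds()
        return ScreenBounds(bounds={b.name: (b.low, b.high)
                                    for b in self.screen_bounds})

    def arm_specs(self) -> list[ArmSpec]:
        if self.arms is None:
            return default_arms()
        return [ArmSpec(a.arm_id,
                        tuple(Regimen(**r.model_dump()) for r in a.regimens),
                        a.horizon_days)
                for a in self.arms]

    def base_params(self) -> ModelParams:
        return ModelParams(**self.model_overrides)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config.

    Unknown keys are rejected with the offending key named; every
    violation is reported, not just the first.  Defaults applied for
    omitted optional fields are visible on the returned object.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"]) or "<root>"
            msgs.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid run config:\n  " + "\n  ".join(msgs)) from exc


def write_manifest(out_dir: str | Path, config: RunConfig,
                   extra: dict | None = None) -> Path:
    """Write a reproducibility manifest (config hash, seeds, version)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = config.model_dump_json().encode()
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "cohort_seed": config.cohort_seed,
        "bootstrap_seed": config.bootstrap_seed,
        **(extra or {}),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


# constructed parameter sets pinning one patient per RECIST class in the
# combination arm (chosen across the TMB ladder at the response boundary)
_SMOKE_CONSTRUCTED: tuple[dict[str, float], ...] = (
    {"n_clones": 150.0, "pdl1_cancer": 6.0e4, "cea_total": 2.0e5, "lam": 6.0},  # CR
    {"n_clones": 90.0, "pdl1_cancer": 6.0e4, "cea_total": 1.0e3, "lam": 1.0},   # PR
    {"n_clones": 86.5, "pdl1_cancer": 6.0e4, "cea_total": 1.0e3, "lam": 1.0},   # SD
    {"n_clones": 5.0, "pdl1_cancer": 6.0e4, "cea_total": 1.0e3, "lam": 1.0},    # PD
)


def make_smoke_fixture(seed: int = 7):
    """Miniature end-to-end fixture: 24 patients, every RECIST class present.

    20 patients are drawn by LHS over the default space; the first four
    are constructed parameter sets placed across the TMB ladder so the
    combination arm contains CR, PR, SD and PD by construction.  Returns
    (cohort, arms).  The full pipeline on this fixture runs in well under
    a minute on one CPU and is deterministic per seed.
    """
    from .model_core import initialize_pretreatment, pretreatment_observables
    from .virtual_cohort import CohortPatient, generate_cohort, screen_patient

    space = default_parameter_space()
    cohort = generate_cohort(space=space, n=24, seed=seed)
    bounds = default_screen_bounds()
    base = ModelParams()
    for i, overrides in enumerate(_SMOKE_CONSTRUCTED):
        params = base.with_updates(**overrides)
        pre = initialize_pretreatment(params)
        obs = pretreatment_observables(pre, params) if not pre.no_tumor else {}
        ok, reasons = screen_patient(pre, obs, bounds)
        sampled = dict(cohort.patients[i].sampled)
        sampled.update(overrides)
        cohort.patients[i] = CohortPatient(
            patient_id=i, params=params, sampled=sampled, plausible=ok,
            reasons=reasons, pre_state=pre, observables=obs)
    return cohort, default_arms()
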