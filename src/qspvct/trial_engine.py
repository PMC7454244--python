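"""Three-arm virtual clinical trial: simulation, RECIST, ORR statistics.

Runs each plausible virtual patient from its identical pre-treatment
state through every study arm, classifies the day-400 percent change of
tumor diameter under simplified RECIST 1.1 rules (single lesion, CR via a
detection floor), and summarizes overall response rates with
Agresti-Coull and percentile-bootstrap confidence intervals.  Subgroup
utilities derive the mono-vs-combination transition labels (PD-SD,
PD-PR/CR, SD-PR/CR, ...) and the three-arm responder groups (ROA, ROC,
ROB, ROCMB, NR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_core import IntegrationError, simulate_patient
from .pharmacokinetics import Regimen
from .virtual_cohort import Cohort

__all__ = [
    "ArmSpec", "ResponseRecord", "TrialResult", "default_arms",
    "classify_recist", "run_trial", "orr_with_ci", "bootstrap_orr_ci",
    "cross_tabulate", "responder_groups",
]

log = logging.getLogger(__name__)

RECIST_CLASSES = ("CR", "PR", "SD", "PD")


@dataclass(frozen=True)
class ArmSpec:
    """One trial arm: identifier, regimens, evaluation horizon."""

    arm_id: str
    regimens: tuple[Regimen, ...]
    horizon_days: float = 400.0


def default_arms() -> list[ArmSpec]:
    """The three study arms: atezolizumab 1200 mg Q3W, cibisatamab
    60 mg QW, and their concurrent combination."""
    atezo = Regimen("atezolizumab", 1200.0, 21.0)
    ciba = Regimen("cibisatamab", 60.0, 7.0)
    return [
        ArmSpec("atezolizumab_mono", (atezo,)),
        ArmSpec("cibisatamab_mono", (ciba,)),
        ArmSpec("combination", (ciba, atezo)),
    ]


@dataclass(frozen=True)
class ResponseRecord:
    patient_id: int
    arm_id: str
    pct_change: float
    recist: str

    @property
    def responder(self) -> bool:
        return self.recist in ("CR", "PR")


@dataclass
class TrialResult:
    """Per-arm response records over plausible patients plus summaries."""

    records: dict[str, list[ResponseRecord]]
    failed: dict[str, list[int]] = field(default_factory=dict)

    def arm(self, arm_id: str) -> list[ResponseRecord]:
        return self.records[arm_id]

    def counts(self, arm_id: str) -> dict[str, int]:
        recs = self.records[arm_id]
        return {
            "PR/CR": sum(r.recist in ("CR", "PR") for r in recs),
            "SD": sum(r.recist == "SD" for r in recs),
            "PD": sum(r.recist == "PD" for r in recs),
            "n": len(recs),
        }

    def orr(self, arm_id: str) -> float:
        recs = self.records[arm_id]
        if not recs:
            return math.nan
        return sum(r.responder for r in recs) / len(recs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": r.patient_id, "arm": r.arm_id,
             "pct_change": r.pct_change, "recist": r.recist}
            for recs in self.records.values() for r in recs
        ]
        return pd.DataFrame(rows)


def classify_recist(d0: float, d_end: float,
                    cr_floor: float = 0.2) -> tuple[str, float]:
    """Simplified single-lesion RECIST 1.1 at one evaluation time.

    pct_change = 100 (d_end - d0) / d0.  CR when the lesion falls below
    the detection floor; otherwise PR at <= -30 %, PD at >= +20 % (both
    thresholds closed), SD in between.
    """
    if d0 <= 0:
        raise ValueError("baseline diameter must be > 0")
    pct = 100.0 * (d_end - d0) / d0
    if d_end < cr_floor:
        return "CR", pct
    if pct <= -30.0:
        return "PR", pct
    if pct >= 20.0:
        return "PD", pct
    return "SD", pct


def run_trial(cohort: Cohort, arms: Sequence[ArmSpec] | None = None,
              grid_step: float = 5.0, cr_floor: float = 0.2,
              rtol: float = 1e-6, atol: float = 1e-3) -> TrialResult:
    """Simulate every plausible patient in every arm.

    Each patient starts every arm from the identical pre-treatment state.
    Patients whose integration fails in an arm are dropped from that
    arm's denominator only, with the failure logged.
    """
    arms = list(arms) if arms is not None else default_arms()
    plausible = cohort.plausible
    if not plausible:
        raise ValueError("cohort has no plausible patients")
    records: dict[str, list[ResponseRecord]] = {a.arm_id: [] for a in arms}
    failed: dict[str, list[int]] = {a.arm_id: [] for a in arms}
    for patient in plausible:
        d0 = patient.observables["tumor_diameter_cm"]
        for arm in arms:
            try:
                traj = simulate_patient(
                    patient.params, arm.regimens, horizon_days=arm.horizon_days,
                    grid_step=grid_step, pre_state=patient.pre_state,
                    rtol=rtol, atol=atol)
            except IntegrationError as exc:
                log.warning("patient %d failed in arm %s: %s",
                            patient.patient_id, arm.arm_id, exc)
                failed[arm.arm_id].append(patient.patient_id)
                continue
            recist, pct = classify_recist(d0, float(traj.diameter_cm[-1]),
                                          cr_floor=cr_floor)
            records[arm.arm_id].append(ResponseRecord(
                patient_id=patient.patient_id, arm_id=arm.arm_id,
                pct_change=pct, recist=recist))
    return TrialResult(records=records, failed=failed)


def orr_with_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float, float]:
    """Overall response rate with the 95 % Agresti-Coull interval.

    n~ = n + z^2, p~ = (k + z^2/2)/n~, CI = p~ +/- z sqrt(p~(1-p~)/n~),
    clipped to [0, 1].  Returns (orr, ci_low, ci_high) as proportions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    n_t = n + z * z
    p_t = (k + z * z / 2.0) / n_t
    half = z * math.sqrt(p_t * (1.0 - p_t) / n_t)
    return k / n, max(0.0, p_t - half), min(1.0, p_t + half)


def bootstrap_orr_ci(responder_flags: Sequence[bool], sample_size: int,
                     reps: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """Percentile-bootstrap 95 % CI of the ORR at a clinical sample size.

    Draws ``sample_size`` patients with replacement ``reps`` times from
    the per-patient responder flags and returns the (2.5th, 97.5th)
    percentiles of the resampled response rates.
    """
    flags = np.asarray(responder_flags, dtype=float)
    if flags.size == 0:
        raise ValueError("responder flags must be non-empty")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, flags.size, size=(reps, sample_size))
    rates = flags[draws].mean(axis=1)
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return float(lo), float(hi)


def _merge_prcr(recist: str) -> str:
    return "PR/CR" if recist in ("CR", "PR") else recist


def cross_tabulate(mono: Iterable[ResponseRecord],
                   combo: Iterable[ResponseRecord]) -> pd.DataFrame:
    """Label each patient's monotherapy-to-combination transition.

    Labels are PD-PD, PD-SD, PD-PR/CR, SD-SD, SD-PR/CR; every other
    class pair (improvement reversals and PR/CR starts) is counted as
    "other" and logged.
    """
    mono_by = {r.patient_id: r for r in mono}
    combo_by = {r.patient_id: r for r in combo}
    if set(mono_by) != set(combo_by):
        raise ValueError("mono and combination arms cover different patients")
    named = {("PD", "PD"): "PD-PD", ("PD", "SD"): "PD-SD",
             ("PD", "PR/CR"): "PD-PR/CR", ("SD", "SD"): "SD-SD",
             ("SD", "PR/CR"): "SD-PR/CR"}
    rows = []
    n_other = 0
    for pid in sorted(mono_by):
        pair = (_merge_prcr(mono_by[pid].recist), _merge_prcr(combo_by[pid].recist))
        label = named.get(pair, "other")
        n_other += label == "other"
        rows.append({"patient_id": pid, "mono": pair[0], "combo": pair[1],
                     "transition": label})
    if n_other:
        log.info("cross_tabulate: %d patients in unnamed transitions", n_other)
    return pd.DataFrame(rows)


def responder_groups(result: TrialResult,
                     atezo_arm: str = "atezolizumab_mono",
                     ciba_arm: str = "cibisatamab_mono",
                     combo_arm: str = "combination") -> pd.DataFrame:
    """Three-arm responder group per patient: ROA, ROC, ROB, ROCMB or NR.

    Responder means PR/CR in that arm.  ROB takes precedence over the
    single-arm labels; ROCMB requires response to the combination only;
    NR means response nowhere.  Patients missing from any arm (solver
    failures) are excluded.
    """
    for arm in (atezo_arm, ciba_arm, combo_arm):
        if arm not in result.records:
            raise ValueError(f"missing arm {arm!r}")
    by_arm = {arm: {r.patient_id: r.responder for r in result.records[arm]}
              for arm in (atezo_arm, ciba_arm, combo_arm)}
    common = set.intersection(*(set(d) for d in by_arm.values()))
    rows = []
    for pid in sorted(common):
        ra = by_arm[atezo_arm][pid]
        rc = by_arm[ciba_arm][pid]
        rm = by_arm[combo_arm][pid]
        if ra and rc:
            group = "ROB"
        elif ra:
            group = "ROA"
        elif rc:
            group = "ROC"
        elif rm:
            group = "ROCMB"
        else:
            group = "NR"
        rows.append({"patient_id": pid, "group": group})
    return pd.DataFrame(rows)
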