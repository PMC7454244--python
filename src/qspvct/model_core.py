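"""Coupled tumor--immune ODE core integrated per virtual patient.

The state tracks cancer cells, dying cells and shed tumor antigen, an
antigen-presenting-cell (APC) maturation chain from the tumor to the
tumor-draining lymph node (TdLN), effector T cells (naive pool, TdLN
activation, central/peripheral/tumor compartments) and a mirrored
regulatory T-cell arm.  Tumor killing proceeds through two routes on the
cancer-cell--Teff synapse: the native TCR route (antigen-restricted,
scaling with the number of activatable T-cell clones, i.e. TMB) and the
T-cell-engager (TCE) trimer route.  Both routes are attenuated by the
PD-1 checkpoint Hill factor on the tumor synapse and by Treg-mediated
suppression; a second checkpoint Hill factor on PD-L1-expressing APCs in
the TdLN shrinks the effective number of proliferation rounds during
priming, which anti-PD-L1 therapy restores.

Drug exposure enters as closed-form plasma PK forcing, gamma-scaled to
tumor and TdLN interstitial concentrations.  The checkpoint and TCE
binding equilibria depend only on local drug concentration and
per-patient receptor totals, so each simulation precomputes Hill-factor
lookup tables over a log-spaced concentration grid; the right-hand side
then costs a handful of interpolations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .pharmacokinetics import (
    DEFAULT_PK, DrugForcing, PKParams, Regimen, build_dose_schedule,
)
from .synapse_binding import (
    CheckpointInputs, HillParams, TCEInputs, hill_checkpoint, hill_tce,
    solve_checkpoint_equilibrium, solve_tce_equilibrium,
)

__all__ = [
    "ModelParams", "ModelState", "Trajectory", "IntegrationError",
    "STATE_NAMES", "tumor_geometry", "cells_from_diameter",
    "initialize_pretreatment", "simulate_patient", "make_rhs",
]

EPS_CELLS = 1.0  # cells, avoids 0/0 in killing denominators

STATE_NAMES = (
    "cancer_cells", "dying_cells", "antigen_pool",
    "apc_immature", "apc_mature_tumor", "apc_mature_ln",
    "t_naive_central", "t_act_ln", "teff_central", "teff_peripheral",
    "teff_tumor", "treg_ln", "treg_central", "treg_tumor",
)


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails; carries the last good time."""

    def __init__(self, message: str, t_last: float | None = None,
                 state: np.ndarray | None = None):
        super().__init__(message)
        self.t_last = t_last
        self.state = state


@dataclass(frozen=True)
class ModelParams:
    """Per-patient model parameters (sampled axes and fixed constants).

    Rates are 1/day, receptor totals sites/cell, volumes cm^3, affinities
    molar.  Sampled cohort axes overwrite the corresponding fields; the
    remaining fields are population constants.
    """

    # -- tumor ------------------------------------------------------------
    k_growth: float = 0.012          # net logistic growth rate
    c_max: float = 1.0e12            # carrying capacity, cells
    d_init: float = 3.0              # pre-treatment target diameter, cm
    vol_cell: float = 2.4e-9         # cm^3 per cancer cell
    packing_fraction: float = 1.0
    k_apoptosis: float = 0.004       # baseline turnover feeding the dying pool
    seed_cells: float = 1.0e6
    t_cap_days: float = 2000.0       # pre-treatment growth horizon

    # -- immunogenicity / activation --------------------------------------
    n_clones: float = 20.0           # TMB: activatable T-cell clones
    k_act: float = 2.0e-6            # activation rate per clone
    n_div: float = 8.0               # proliferation generations at full priming
    k_pro: float = 1.0               # TdLN effector output rate
    n_clone_half: float = 106.0       # half-max clones for TCR recognition
    n_clone_exp: float = 4.0

    # -- antigen / APC chain ----------------------------------------------
    k_release: float = 1.0           # antigen units per dying cell per day
    k_uptake: float = 1.0e-6         # per APC per day
    k_deg: float = 10.0              # free antigen degradation
    k_mat: float = 1.0               # APC maturation at full antigen signal
    k_mig: float = 0.5               # mature APC migration to TdLN
    k_clear: float = 0.5             # dying-cell clearance
    s_apc: float = 1.0e5             # immature APC supply, cells/day
    k_death_apc: float = 0.1
    k_death_apc_ln: float = 0.5

    # -- T effector pools / trafficking ------------------------------------
    naive_pool: float = 5.0e9        # steady naive T cells in blood
    k_death_naive: float = 0.03
    k_cp: float = 0.1                # central -> peripheral
    k_pc: float = 0.05               # peripheral -> central
    k_death_teff_central: float = 0.1
    k_death_teff_peripheral: float = 0.05
    q_in: float = 0.5                # infiltration scale, x (C/c_max)^(2/3)
    q_out: float = 0.03              # tumor egress
    k_death_teff: float = 0.065       # intratumoral Teff death
    k_pro_teff_tumor: float = 0.34    # synapse-driven intratumoral expansion
    teff_cap_fraction: float = 0.05  # Teff carrying capacity as fraction of C

    # -- regulatory T cells -------------------------------------------------
    treg_activity: float = 1.0       # multiplier on Treg activation
    k_act_treg: float = 1.0e-6
    treg_pool: float = 1.0e10
    k_pro_treg: float = 1.0
    n_div_treg: float = 4.0
    q_in_treg: float = 0.25
    q_out_treg: float = 0.02
    k_death_treg_central: float = 0.1
    k_death_treg: float = 0.05
    k_treg_suppress: float = 1.2

    # -- killing ------------------------------------------------------------
    k_kill_tcr: float = 2.6
    k_kill_tce: float = 7.0
    w_tce_checkpoint: float = 0.05    # PD-1 weight on the TCE route (partial bypass)

    # -- receptors / binding -----------------------------------------------
    pd1_total: float = 3.0e3
    pdl1_cancer: float = 5.0e3
    pdl1_apc: float = 1.0e4
    cea_total: float = 1.0e5
    cd3_total: float = 5.0e4
    r_pdl2: float = 0.035
    chi: float = 1.0
    lam: float = 2.0
    delta: float = 1.0
    kd_pd1_pdl1: float = 2000.0
    kd_pd1_pdl2: float = 5.0e4
    kd_drug_atezolizumab: float = 4.0e-10
    kd_cea: float = 5.0e-9
    kd_cd3: float = 1.0e-7
    contact_area_scale: float = 2.0e11

    # -- Hill transductions ------------------------------------------------
    # checkpoint and TCE Hills act on fractional receptor occupancy
    # (PD-1-complex / PD-1 total; trimer / CD3 total), so efficacy does not
    # depend on absolute receptor copy number, only on engagement
    h_pd1_half_occ: float = 0.20     # tumor-synapse checkpoint half-max occupancy
    h_pd1_n: float = 2.5
    h_pd1_ln_half_occ: float = 0.20  # priming checkpoint on APCs
    h_pd1_ln_n: float = 2.5
    h_tce_half_occ: float = 0.23      # trimer half-max CD3 occupancy
    h_tce_n: float = 3.0
    h_antigen_khalf: float = 1.0e7   # antigen -> APC maturation
    h_apc_khalf: float = 2.0e5       # mature APC in TdLN -> activation
    h_treg_khalf: float = 1.0e4      # Treg density (cells/cm^3) -> suppression

    # -- bookkeeping ---------------------------------------------------------
    blood_volume_ul: float = 5.0e6

    def __post_init__(self) -> None:
        if self.d_init <= 0:
            raise ValueError("d_init must be > 0")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and (v < 0 or math.isnan(v)):
                raise ValueError(f"{f.name} must be non-negative, got {v!r}")

    def with_updates(self, **kwargs: float) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class ModelState:
    """Named view of one state vector (all counts/amounts, non-negative)."""

    values: np.ndarray
    no_tumor: bool = False

    def __getattr__(self, name: str) -> float:
        try:
            return float(self.values[STATE_NAMES.index(name)])
        except ValueError as exc:  # pragma: no cover
            raise AttributeError(name) from exc

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STATE_NAMES, map(float, self.values)))


@dataclass
class Trajectory:
    """Time-gridded solution plus derived observables."""

    times: np.ndarray                # days
    states: np.ndarray               # (n_states, n_times)
    diameter_cm: np.ndarray
    teff_density_tumor: np.ndarray   # cells/cm^3
    treg_density_tumor: np.ndarray
    teff_treg_ratio: np.ndarray
    conc_atezolizumab: np.ndarray    # plasma, molar
    conc_cibisatamab: np.ndarray

    def state(self, name: str) -> np.ndarray:
        return self.states[STATE_NAMES.index(name)]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def tumor_geometry(cancer_cells: float, p: ModelParams) -> tuple[float, float]:
    """Map cancer-cell count to (volume cm^3, equivalent-sphere diameter cm)."""
    if cancer_cells < 0:
        raise ValueError("cancer_cells must be >= 0")
    volume = cancer_cells * p.vol_cell / p.packing_fraction
    diameter = (6.0 * volume / math.pi) ** (1.0 / 3.0)
    return volume, diameter


def cells_from_diameter(diameter_cm: float, p: ModelParams) -> float:
    """Exact inverse of :func:`tumor_geometry`."""
    volume = math.pi / 6.0 * diameter_cm ** 3
    return volume * p.packing_fraction / p.vol_cell


# ---------------------------------------------------------------------------
# Hill-factor lookup tables over drug concentration
# ---------------------------------------------------------------------------

_LOG_GRID = np.linspace(-16.0, -4.0, 121)  # log10 molar


class _HillTables:
    """Per-patient checkpoint/TCE Hill factors vs local drug concentration."""

    def __init__(self, p: ModelParams):
        self.p = p
        hp_syn = HillParams(p.h_pd1_half_occ * p.pd1_total, p.h_pd1_n, p.delta)
        hp_ln = HillParams(p.h_pd1_ln_half_occ * p.pd1_total, p.h_pd1_ln_n,
                           p.delta)
        self._h_syn = self._checkpoint_curve(p.pdl1_cancer, hp_syn)
        self._h_ln = self._checkpoint_curve(p.pdl1_apc, hp_ln)
        self._h_tce = self._tce_curve()

    def _checkpoint_curve(self, pdl1_total: float, hp: HillParams) -> np.ndarray:
        p = self.p
        vals = np.empty(_LOG_GRID.size + 1)
        for i, conc in enumerate(np.concatenate([[0.0], 10.0 ** _LOG_GRID])):
            cx = solve_checkpoint_equilibrium(CheckpointInputs(
                pd1_total=p.pd1_total, pdl1_total=pdl1_total, r_pdl2=p.r_pdl2,
                drug_conc=conc, chi=p.chi, kd_pd1_pdl1=p.kd_pd1_pdl1,
                kd_pd1_pdl2=p.kd_pd1_pdl2, kd_drug=p.kd_drug_atezolizumab,
                contact_area_scale=p.contact_area_scale))
            vals[i] = hill_checkpoint(cx, hp)
        return vals

    def _tce_curve(self) -> np.ndarray:
        p = self.p
        hp = HillParams(p.h_tce_half_occ * p.cd3_total, p.h_tce_n)
        vals = np.empty(_LOG_GRID.size + 1)
        for i, conc in enumerate(np.concatenate([[0.0], 10.0 ** _LOG_GRID])):
            sp = solve_tce_equilibrium(TCEInputs(
                cea_total=p.cea_total, cd3_total=p.cd3_total, tce_conc=conc,
                lam=p.lam, kd_cea=p.kd_cea, kd_cd3=p.kd_cd3,
                contact_area_scale=p.contact_area_scale))
            vals[i] = hill_tce(sp, hp)
        return vals

    @staticmethod
    def _lookup(table: np.ndarray, conc: float) -> float:
        if conc <= 1e-16:
            return table[0]
        return float(np.interp(math.log10(conc), _LOG_GRID, table[1:]))

    def h_pd1_syn(self, conc: float) -> float:
        return self._lookup(self._h_syn, conc)

    def h_pd1_ln(self, conc: float) -> float:
        return self._lookup(self._h_ln, conc)

    def h_tce(self, conc: float) -> float:
        return self._lookup(self._h_tce, conc)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def make_rhs(p: ModelParams,
             forcing_atezolizumab: DrugForcing | None = None,
             forcing_cibisatamab: DrugForcing | None = None,
             tables: _HillTables | None = None):
    """Build the ODE right-hand side f(t, y) for one patient.

    Drug forcings may be None (drug absent).  Fluxes are computed from
    states floored at zero, which keeps the system forward-invariant on
    the non-negative orthant up to integrator tolerance.
    """
    tb = tables if tables is not None else _HillTables(p)
    # hoist attribute lookups out of the hot loop
    kg, cmax, kapo = p.k_growth, p.c_max, p.k_apoptosis
    vol_scale = p.vol_cell / p.packing_fraction
    hclone = p.n_clones ** p.n_clone_exp / (
        p.n_clones ** p.n_clone_exp + p.n_clone_half ** p.n_clone_exp)
    kact_n = p.k_act * p.n_clones
    s_naive = p.naive_pool * p.k_death_naive
    kact_r = p.k_act_treg * p.treg_activity
    amp_r = 2.0 ** p.n_div_treg
    has_atezo = forcing_atezolizumab is not None
    has_ciba = forcing_cibisatamab is not None
    h_syn0 = tb.h_pd1_syn(0.0)
    h_ln0 = tb.h_pd1_ln(0.0)

    def rhs(t: float, y: Sequence[float]) -> list[float]:
        (C, D, Ag, APCi, APCt, APCln, Tn, Tact, Tec, Tep, Tet,
         Rln, Rc, Rt) = (v if v > 0.0 else 0.0 for v in y)

        if has_atezo:
            ca = forcing_atezolizumab.central(t)
            h_syn = tb.h_pd1_syn(ca * forcing_atezolizumab.pk.gamma_tumor)
            h_ln = tb.h_pd1_ln(ca * forcing_atezolizumab.pk.gamma_ln)
        else:
            h_syn, h_ln = h_syn0, h_ln0
        if has_ciba:
            h_tce = tb.h_tce(forcing_cibisatamab.tumor(t))
        else:
            h_tce = 0.0

        v_tumor = C * vol_scale
        treg_density = Rt / v_tumor if v_tumor > 0 else 0.0
        h_treg = treg_density / (treg_density + p.h_treg_khalf)
        treg_factor = 1.0 / (1.0 + p.k_treg_suppress * h_treg)
        # both routes need tumor-reactive T cells (clonal factor); the TCR
        # route is fully checkpoint-suppressed while the MHC-independent TCE
        # synapse is only partially so (weight w_tce_checkpoint)
        drive = hclone * (p.k_kill_tcr * (1.0 - h_syn)
                          + p.k_kill_tce * h_tce
                          * (1.0 - p.w_tce_checkpoint * h_syn))
        k_total = drive * treg_factor * (Tet / (C + Tet + EPS_CELLS))
        # synapse engagement (TCR recognition or TCE trimer) also drives local
        # Teff proliferation, limited by a tumor-size-proportional capacity
        room = 1.0 - Tet / (p.teff_cap_fraction * C + EPS_CELLS)
        engage = hclone * ((1.0 - h_syn)
                           + h_tce * (1.0 - p.w_tce_checkpoint * h_syn))
        expand = (p.k_pro_teff_tumor * engage * treg_factor
                  * Tet * (room if room > 0.0 else 0.0))

        h_ant = Ag / (Ag + p.h_antigen_khalf)
        h_apc = APCln / (APCln + p.h_apc_khalf)
        act_flux = kact_n * h_apc * Tn
        amp = 2.0 ** (p.n_div * (1.0 - h_ln))
        infiltr = p.q_in * (C / cmax) ** (2.0 / 3.0)
        infiltr_r = p.q_in_treg * (C / cmax) ** (2.0 / 3.0)
        act_flux_r = kact_r * h_apc * p.treg_pool

        kill = k_total * C
        dC = kg * C * (1.0 - C / cmax) - kill
        dD = kill + kapo * C - p.k_clear * D
        dAg = p.k_release * D - p.k_uptake * Ag * APCi - p.k_deg * Ag
        dAPCi = p.s_apc - p.k_mat * h_ant * APCi - p.k_death_apc * APCi
        dAPCt = p.k_mat * h_ant * APCi - p.k_mig * APCt - p.k_death_apc * APCt
        dAPCln = p.k_mig * APCt - p.k_death_apc_ln * APCln
        dTn = s_naive - p.k_death_naive * Tn - act_flux
        dTact = act_flux - p.k_pro * Tact
        dTec = (amp * p.k_pro * Tact - (infiltr + p.k_cp + p.k_death_teff_central) * Tec
                + p.k_pc * Tep)
        dTep = p.k_cp * Tec - (p.k_pc + p.k_death_teff_peripheral) * Tep
        dTet = infiltr * Tec + expand - (p.q_out + p.k_death_teff) * Tet
        dRln = act_flux_r - p.k_pro_treg * Rln
        dRc = (amp_r * p.k_pro_treg * Rln
               - (infiltr_r + p.k_death_treg_central) * Rc)
        dRt = infiltr_r * Rc - (p.q_out_treg + p.k_death_treg) * Rt

        return [dC, dD, dAg, dAPCi, dAPCt, dAPCln, dTn, dTact, dTec, dTep,
                dTet, dRln, dRc, dRt]

    return rhs


def _initial_state(p: ModelParams) -> np.ndarray:
    y0 = np.zeros(len(STATE_NAMES))
    y0[STATE_NAMES.index("cancer_cells")] = p.seed_cells
    y0[STATE_NAMES.index("apc_immature")] = p.s_apc / p.k_death_apc
    y0[STATE_NAMES.index("t_naive_central")] = p.naive_pool
    return y0


def initialize_pretreatment(p: ModelParams, rtol: float = 1e-6,
                            atol: float = 1e-3,
                            tables: _HillTables | None = None) -> ModelState:
    """Grow a seed tumor without treatment until it reaches ``d_init``.

    Integrates the drug-free system from a small seed until the tumor
    diameter first crosses ``d_init`` or the growth horizon ``t_cap_days``
    elapses.  Returns the state at first crossing, or the final state
    flagged ``no_tumor`` if the tumor never reaches the target size
    (slow growth or immune control).
    """
    c_target = cells_from_diameter(p.d_init, p)
    rhs = make_rhs(p, tables=tables)

    def crossed(t, y):
        return y[0] - c_target

    crossed.terminal = True
    crossed.direction = 1.0
    y0 = _initial_state(p)
    if y0[0] >= c_target:
        return ModelState(values=y0, no_tumor=False)
    sol = solve_ivp(rhs, (0.0, p.t_cap_days), y0, method="LSODA",
                    events=crossed, rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:
        raise IntegrationError(
            f"pre-treatment integration failed: {sol.message}; params={p!r}",
            t_last=float(sol.t[-1]) if sol.t.size else None)
    if sol.t_events[0].size:
        y = np.clip(sol.y_events[0][0], 0.0, None)
        return ModelState(values=y, no_tumor=False)
    y = np.clip(sol.y[:, -1], 0.0, None)
    return ModelState(values=y, no_tumor=True)


def simulate_patient(p: ModelParams, regimens: Sequence[Regimen],
                     horizon_days: float = 400.0, grid_step: float = 5.0,
                     pre_state: ModelState | None = None,
                     pk_params: dict[str, PKParams] | None = None,
                     rtol: float = 1e-6, atol: float = 1e-3,
                     max_step_dosing: float = 1.0) -> Trajectory:
    """Simulate one patient under treatment from day 0 to the horizon.

    Day 0 is the first treatment day; the pre-treatment state (computed
    here if not supplied) is the initial condition.  PK forcing is the
    closed-form two-compartment superposition; the integrator is
    stiff-capable (LSODA) with the maximum step bounded during dosing so
    no bolus is stepped over.
    """
    pk_params = pk_params or DEFAULT_PK
    tables = _HillTables(p)
    if pre_state is None:
        pre_state = initialize_pretreatment(p, rtol=rtol, atol=atol,
                                            tables=tables)
    if pre_state.no_tumor:
        raise ValueError("cannot treat a patient flagged no_tumor")

    forcings: dict[str, DrugForcing | None] = {"atezolizumab": None,
                                               "cibisatamab": None}
    any_dose = False
    for drug in forcings:
        regs = [r for r in regimens if r.drug_id == drug]
        schedule = []
        for r in regs:
            schedule.extend(build_dose_schedule(r, horizon_days,
                                                pk_params[drug].mw))
        if schedule:
            schedule.sort(key=lambda e: e.time)
            forcings[drug] = DrugForcing(schedule, pk_params[drug])
            any_dose = True

    rhs = make_rhs(p, forcing_atezolizumab=forcings["atezolizumab"],
                   forcing_cibisatamab=forcings["cibisatamab"], tables=tables)
    t_eval = np.arange(0.0, horizon_days + 0.5 * grid_step, grid_step)
    t_eval[-1] = min(t_eval[-1], horizon_days)
    kwargs = dict(method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if any_dose:
        kwargs["max_step"] = max_step_dosing
    sol = solve_ivp(rhs, (0.0, horizon_days), pre_state.values, **kwargs)
    if not sol.success:
        raise IntegrationError(
            f"treatment integration failed: {sol.message}",
            t_last=float(sol.t[-1]) if sol.t.size else 0.0,
            state=sol.y[:, -1] if sol.y.size else None)

    states = np.clip(sol.y, 0.0, None)
    cells = states[STATE_NAMES.index("cancer_cells")]
    vol = cells * p.vol_cell / p.packing_fraction
    diameter = (6.0 * vol / math.pi) ** (1.0 / 3.0)
    tet = states[STATE_NAMES.index("teff_tumor")]
    rt = states[STATE_NAMES.index("treg_tumor")]
    with np.errstate(divide="ignore", invalid="ignore"):
        teff_density = np.where(vol > 0, tet / vol, 0.0)
        treg_density = np.where(vol > 0, rt / vol, 0.0)
        ratio = np.where(rt > 0, tet / np.maximum(rt, 1e-300), np.inf)

    conc = {}
    for drug, f in forcings.items():
        if f is None:
            conc[drug] = np.zeros_like(sol.t)
        else:
            conc[drug] = np.array([f.central(t) for t in sol.t])

    return Trajectory(
        times=sol.t, states=states, diameter_cm=diameter,
        teff_density_tumor=teff_density, treg_density_tumor=treg_density,
        teff_treg_ratio=ratio,
        conc_atezolizumab=conc["atezolizumab"],
        conc_cibisatamab=conc["cibisatamab"],
    )


def pretreatment_observables(state: ModelState, p: ModelParams) -> dict[str, float]:
    """Screening observables derived from a pre-treatment state."""
    vol, diameter = tumor_geometry(state.cancer_cells, p)
    blood_t = ((state.t_naive_central + state.teff_central + state.treg_central)
               / p.blood_volume_ul)
    teff_density = state.teff_tumor / vol if vol > 0 else 0.0
    ratio = (state.teff_tumor / state.treg_tumor
             if state.treg_tumor > 0 else math.inf)
    return {
        "tumor_diameter_cm": diameter,
        "blood_t_density": blood_t,
        "tumor_activated_t_density": teff_density,
        "teff_treg_ratio": ratio,
    }
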