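"""Quasi-steady-state binding models for the immunological synapse.

Two algebraic sub-models are solved here, both on a sites-per-cell scale:

* the PD-1 / PD-L1 / PD-L2 checkpoint axis on a Teff--target-cell contact,
  with a bivalent anti-PD-L1 antibody competing for PD-L1.  The antibody
  binds monovalently from solution (dissociation constant ``kd_drug``,
  molar) and can then capture a second PD-L1 with its free arm; the
  cross-arm step is an avidity-enhanced 2-D equilibrium whose dissociation
  constant is ``kd_drug * contact_area_scale / chi`` (sites/cell), where
  ``chi`` is the cross-arm binding efficiency.  PD-L2 binds PD-1 but is
  not bound by the drug.

* the CEA x CD3 T-cell-engager (TCE) synapse.  The TCE binds CEA on the
  cancer cell and CD3 on the Teff from solution, and either dimer can be
  cross-linked into the cytolytic trimer; the cross-arm steps use the
  efficiency ``lam`` and are thermodynamic-cycle consistent, so the trimer
  density is path independent.

Bound-complex densities are converted into Hill activation/inhibition
factors consumed by the ODE core.  Receptor totals are per-cell copy
numbers; drug concentrations are molar and assumed not depleted by
surface binding (antibody is in vast molar excess over synapse sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CheckpointInputs",
    "CheckpointComplexes",
    "TCEInputs",
    "TCESpecies",
    "HillParams",
    "BindingSolverError",
    "solve_checkpoint_equilibrium",
    "hill_checkpoint",
    "solve_tce_equilibrium",
    "hill_tce",
]

#: relative mass-balance tolerance enforced by both solvers
MASS_BALANCE_RTOL = 1e-8


class BindingSolverError(RuntimeError):
    """Raised when an equilibrium solve fails to meet mass balance."""

    def __init__(self, message: str, residuals: dict[str, float] | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


def _require_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0 or math.isnan(value):
            raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class CheckpointInputs:
    """Inputs of the checkpoint equilibrium on one synapse type.

    ``pd1_total`` is sites per Teff cell, ``pdl1_total`` sites per target
    cell (cancer cell or APC).  PD-L2 is slaved to PD-L1 through the
    per-patient ratio ``r_pdl2`` in [0, 0.07].  ``kd_pd1_pdl1`` and
    ``kd_pd1_pdl2`` are 2-D dissociation constants already on the
    sites/cell scale; ``kd_drug`` is molar.
    """

    pd1_total: float
    pdl1_total: float
    r_pdl2: float = 0.0
    drug_conc: float = 0.0
    chi: float = 1.0
    kd_pd1_pdl1: float = 1000.0
    kd_pd1_pdl2: float = 300.0
    kd_drug: float = 4.0e-10
    contact_area_scale: float = 1.0e12

    def __post_init__(self) -> None:
        _require_nonneg(
            pd1_total=self.pd1_total,
            pdl1_total=self.pdl1_total,
            drug_conc=self.drug_conc,
            chi=self.chi,
        )
        if not (0.0 <= self.r_pdl2 <= 0.07):
            raise ValueError(f"r_pdl2 must lie in [0, 0.07], got {self.r_pdl2!r}")
        if self.kd_pd1_pdl1 <= 0 or self.kd_pd1_pdl2 <= 0 or self.kd_drug <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.contact_area_scale <= 0:
            raise ValueError("contact_area_scale must be positive")

    @property
    def pdl2_total(self) -> float:
        return self.r_pdl2 * self.pdl1_total


@dataclass(frozen=True)
class CheckpointComplexes:
    """Equilibrium complex densities (sites/cell) on one synapse."""

    c_pd1_pdl1: float
    c_pd1_pdl2: float
    c_drug_pdl1_mono: float
    c_drug_pdl1_cross: float
    free_pd1: float
    free_pdl1: float
    free_pdl2: float


@dataclass(frozen=True)
class TCEInputs:
    """Inputs of the TCE trimer equilibrium on a cancer-cell--Teff synapse."""

    cea_total: float
    cd3_total: float
    tce_conc: float = 0.0
    lam: float = 1.0
    kd_cea: float = 5.0e-9
    kd_cd3: float = 1.0e-7
    contact_area_scale: float = 1.0e12

    def __post_init__(self) -> None:
        _require_nonneg(
            cea_total=self.cea_total,
            cd3_total=self.cd3_total,
            tce_conc=self.tce_conc,
            lam=self.lam,
        )
        if self.kd_cea <= 0 or self.kd_cd3 <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.contact_area_scale <= 0:
            raise ValueError("contact_area_scale must be positive")


@dataclass(frozen=True)
class TCESpecies:
    """Equilibrium TCE species densities (sites/cell)."""

    dimer_cea: float
    dimer_cd3: float
    trimer: float
    free_cea: float
    free_cd3: float


@dataclass(frozen=True)
class HillParams:
    """Hill transduction of a complex density into a factor in [0, 1].

    ``delta`` weights the PD-1:PD-L2 complex inside the checkpoint Hill
    argument (S = C_PD1-PDL1 + delta * C_PD1-PDL2); it is ignored by the
    TCE Hill.
    """

    k_half: float
    n_hill: float = 1.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.k_half <= 0:
            raise ValueError("k_half must be positive")
        if self.n_hill < 1:
            raise ValueError("n_hill must be >= 1")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")


# ---------------------------------------------------------------------------
# checkpoint equilibrium
# ---------------------------------------------------------------------------

def _checkpoint_free_pd1(p_tot: float, l1f: float, l2_tot: float,
                         k1: float, k2: float) -> float:
    """Free PD-1 given free PD-L1, solving the PD-1/PD-L2 sub-system.

    With L2f = L2tot / (1 + P/K2) substituted into PD-1 conservation the
    free PD-1 satisfies b*P^2 + (b*K2 + L2tot - Ptot)*P - Ptot*K2 = 0
    with b = 1 + L1f/K1; the positive root is returned.
    """
    b = 1.0 + l1f / k1
    bb = b * k2 + l2_tot - p_tot
    cc = -p_tot * k2
    disc = bb * bb - 4.0 * b * cc
    # cc <= 0 so disc >= bb^2; numerically stable positive root
    q = -0.5 * (bb + math.copysign(math.sqrt(disc), bb)) if bb != 0 else math.sqrt(-b * cc)
    r1 = q / b
    r2 = cc / q if q != 0 else 0.0
    return max(r1, r2)


def solve_checkpoint_equilibrium(inp: CheckpointInputs) -> CheckpointComplexes:
    """Solve the simultaneous checkpoint equilibrium.

    Reactions (all sites/cell except the solution-phase drug step):

    * PD1 + PDL1  <-> C1      (kd_pd1_pdl1)
    * PD1 + PDL2  <-> C2      (kd_pd1_pdl2)
    * Drug + PDL1 <-> D1      (kd_drug, molar; drug not depleted)
    * D1 + PDL1   <-> D2      (kd_drug * contact_area_scale / chi)

    Solved by a bracketed root-find on free PD-L1 with the PD-1/PD-L2
    sub-system eliminated in closed form at each iterate.  Mass balances
    are verified to ``MASS_BALANCE_RTOL``.
    """
    p_tot, l1_tot, l2_tot = inp.pd1_total, inp.pdl1_total, inp.pdl2_total
    k1, k2 = inp.kd_pd1_pdl1, inp.kd_pd1_pdl2
    a = inp.drug_conc / inp.kd_drug  # dimensionless monovalent occupancy driver
    kd2d = inp.kd_drug * inp.contact_area_scale  # 2-D scale for the cross-arm step
    cross = inp.chi * a / kd2d  # D2 = cross * L1f^2

    if l1_tot == 0.0:
        # no PD-L1 implies no PD-L2 either (slaved through r_pdl2)
        return CheckpointComplexes(0.0, 0.0, 0.0, 0.0, p_tot, 0.0, 0.0)

    def residual(l1f: float) -> float:
        p = _checkpoint_free_pd1(p_tot, l1f, l2_tot, k1, k2)
        c1 = p * l1f / k1
        d1 = a * l1f
        d2 = cross * l1f * l1f
        return l1f + c1 + d1 + 2.0 * d2 - l1_tot

    # residual is continuous, strictly increasing, residual(0) = -l1_tot < 0
    lo, hi = 0.0, l1_tot
    if residual(hi) < 0:  # cannot happen analytically; guard for fp noise
        hi = l1_tot * (1.0 + 1e-12)
    from scipy.optimize import brentq

    l1f = brentq(residual, lo, hi, xtol=1e-14 * max(l1_tot, 1.0), rtol=8.9e-16,
                 maxiter=200)

    p = _checkpoint_free_pd1(p_tot, l1f, l2_tot, k1, k2)
    l2f = l2_tot / (1.0 + p / k2) if l2_tot > 0 else 0.0
    c1 = p * l1f / k1
    c2 = p * l2f / k2
    d1 = a * l1f
    d2 = cross * l1f * l1f

    out = CheckpointComplexes(
        c_pd1_pdl1=c1, c_pd1_pdl2=c2, c_drug_pdl1_mono=d1,
        c_drug_pdl1_cross=d2, free_pd1=p, free_pdl1=l1f, free_pdl2=l2f,
    )
    _check_checkpoint_balance(inp, out)
    return out


def _check_checkpoint_balance(inp: CheckpointInputs, cx: CheckpointComplexes) -> None:
    res = {}
    if inp.pd1_total > 0:
        res["pd1"] = abs(cx.free_pd1 + cx.c_pd1_pdl1 + cx.c_pd1_pdl2 - inp.pd1_total) / inp.pd1_total
    if inp.pdl1_total > 0:
        res["pdl1"] = abs(
            cx.free_pdl1 + cx.c_pd1_pdl1 + cx.c_drug_pdl1_mono
            + 2.0 * cx.c_drug_pdl1_cross - inp.pdl1_total
        ) / inp.pdl1_total
    if inp.pdl2_total > 0:
        res["pdl2"] = abs(cx.free_pdl2 + cx.c_pd1_pdl2 - inp.pdl2_total) / inp.pdl2_total
    if any(r > MASS_BALANCE_RTOL for r in res.values()):
        raise BindingSolverError("checkpoint equilibrium violates mass balance", res)


def hill_checkpoint(cx: CheckpointComplexes, hp: HillParams) -> float:
    """Checkpoint inhibition factor H in [0, 1].

    The Hill argument is S = C_PD1-PDL1 + delta * C_PD1-PDL2 so that
    delta = 0 reduces the model to PD-L1-only signalling.  Downstream the
    killing/proliferation modifier is (1 - H).
    """
    s = cx.c_pd1_pdl1 + hp.delta * cx.c_pd1_pdl2
    if s <= 0.0:
        return 0.0
    # compute in a ratio form immune to overflow for large s
    ratio = (hp.k_half / s) ** hp.n_hill
    return 1.0 / (1.0 + ratio)


# ---------------------------------------------------------------------------
# TCE trimer equilibrium
# ---------------------------------------------------------------------------

def solve_tce_equilibrium(inp: TCEInputs) -> TCESpecies:
    """Solve the CEA x TCE x CD3 trimer equilibrium.

    Reactions (drug in solution, not depleted):

    * TCE + CEA       <-> dimer_cea   (kd_cea)
    * TCE + CD3       <-> dimer_cd3   (kd_cd3)
    * dimer_cea + CD3 <-> trimer      (kd_cd3 * contact_area_scale / lam)
    * dimer_cd3 + CEA <-> trimer      (kd_cea * contact_area_scale / lam)

    The two trimer paths close a thermodynamic cycle, so the equilibrium
    trimer density trimer = lam * A * Rf * Tf / (kd_cea * kd_cd3 * cas)
    is path independent (detailed balance).  The remaining conservation
    system reduces to one quadratic in free CD3, solved in closed form.
    """
    r_tot, t_tot = inp.cea_total, inp.cd3_total
    alpha = inp.tce_conc / inp.kd_cea  # free-CEA monovalent occupancy driver
    beta = inp.tce_conc / inp.kd_cd3
    g = inp.lam * inp.tce_conc / (inp.kd_cea * inp.kd_cd3 * inp.contact_area_scale)

    if r_tot == 0.0 or t_tot == 0.0 or inp.tce_conc == 0.0:
        rf = r_tot / (1.0 + alpha)
        tf = t_tot / (1.0 + beta)
        return TCESpecies(alpha * rf, beta * tf, 0.0, rf, tf)

    if g == 0.0:  # lam == 0: monovalent dimers only, no synapse
        rf = r_tot / (1.0 + alpha)
        tf = t_tot / (1.0 + beta)
        out = TCESpecies(alpha * rf, beta * tf, 0.0, rf, tf)
        _check_tce_balance(inp, out)
        return out

    # substitute Rf = Rtot / (1 + alpha + g*Tf) into CD3 conservation:
    # g(1+beta) Tf^2 + [(1+alpha)(1+beta) + g(Rtot - Ttot)] Tf - Ttot(1+alpha) = 0
    a2 = g * (1.0 + beta)
    b2 = (1.0 + alpha) * (1.0 + beta) + g * (r_tot - t_tot)
    c2 = -t_tot * (1.0 + alpha)
    disc = b2 * b2 - 4.0 * a2 * c2
    sq = math.sqrt(disc)
    q = -0.5 * (b2 + math.copysign(sq, b2)) if b2 != 0 else -0.5 * sq
    roots = [q / a2]
    if q != 0:
        roots.append(c2 / q)
    tf = max(r for r in roots)
    tf = min(max(tf, 0.0), t_tot)

    rf = r_tot / (1.0 + alpha + g * tf)
    tri = g * rf * tf
    out = TCESpecies(
        dimer_cea=alpha * rf, dimer_cd3=beta * tf, trimer=tri,
        free_cea=rf, free_cd3=tf,
    )
    _check_tce_balance(inp, out)
    return out


def _check_tce_balance(inp: TCEInputs, sp: TCESpecies) -> None:
    res = {}
    if inp.cea_total > 0:
        res["cea"] = abs(sp.free_cea + sp.dimer_cea + sp.trimer - inp.cea_total) / inp.cea_total
    if inp.cd3_total > 0:
        res["cd3"] = abs(sp.free_cd3 + sp.dimer_cd3 + sp.trimer - inp.cd3_total) / inp.cd3_total
    if any(r > MASS_BALANCE_RTOL for r in res.values()):
        raise BindingSolverError("TCE equilibrium violates mass balance", res)


def hill_tce(sp: TCESpecies, hp: HillParams) -> float:
    """TCE killing activation factor H in [0, 1] from the trimer density."""
    if sp.trimer <= 0.0:
        return 0.0
    ratio = (hp.k_half / sp.trimer) ** hp.n_hill
    return 1.0 / (1.0 + ratio)
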