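"""ODE core: geometry, oracles, monotonicities, trajectory invariants."""

import math

import numpy as np
import pytest

from qspvct.model_core import (
    ModelParams, ModelState, STATE_NAMES, _HillTables, cells_from_diameter,
    initialize_pretreatment, pretreatment_observables, simulate_patient,
    tumor_geometry,
)
from qspvct.pharmacokinetics import Regimen
from qspvct.trial_engine import default_arms

ATEZO = Regimen("atezolizumab", 1200.0, 21.0)
CIBA = Regimen("cibisatamab", 60.0, 7.0)


def _state_with_cells(cells: float) -> ModelState:
    y = np.zeros(len(STATE_NAMES))
    y[0] = cells
    y[STATE_NAMES.index("t_naive_central")] = 5e9
    y[STATE_NAMES.index("apc_immature")] = 1e6
    return ModelState(values=y)


class TestGeometry:
    def test_zero_cells(self):
        assert tumor_geometry(0.0, ModelParams()) == (0.0, 0.0)

    def test_sphere_identity(self):
        """pi/6 cm^3 of tumor is a 1 cm sphere."""
        p = ModelParams()
        cells = (math.pi / 6.0) * p.packing_fraction / p.vol_cell
        vol, diam = tumor_geometry(cells, p)
        assert vol == pytest.approx(math.pi / 6.0, rel=1e-12)
        assert diam == pytest.approx(1.0, rel=1e-12)

    def test_roundtrip_inverse(self):
        p = ModelParams()
        rng = np.random.default_rng(0)
        for cells in 10 ** rng.uniform(0, 12, size=100):
            _, d = tumor_geometry(cells, p)
            assert cells_from_diameter(d, p) == pytest.approx(cells, rel=1e-12)


class TestRhsOracles:
    def test_logistic_closed_form_when_killing_disabled(self):
        """With both killing routes off the cancer compartment decouples
        and follows the logistic closed form."""
        p = ModelParams(k_kill_tcr=0.0, k_kill_tce=0.0)
        c0 = cells_from_diameter(3.0, p)
        pre = _state_with_cells(c0)
        traj = simulate_patient(p, [], horizon_days=100.0, grid_step=100.0,
                                pre_state=pre, rtol=1e-9, atol=1e-6)
        c100 = traj.state("cancer_cells")[-1]
        expected = p.c_max / (1.0 + (p.c_max / c0 - 1.0)
                              * math.exp(-p.k_growth * 100.0))
        assert c100 == pytest.approx(expected, rel=1e-6)

    def test_zero_dose_tce_identical_to_atezo_mono(self):
        """A zero-mg cibisatamab regimen leaves the trajectory bit-identical
        to atezolizumab monotherapy (forcing identity)."""
        p = ModelParams()
        pre = initialize_pretreatment(p)
        t1 = simulate_patient(p, [ATEZO], pre_state=pre)
        t2 = simulate_patient(p, [ATEZO, Regimen("cibisatamab", 0.0, 7.0)],
                              pre_state=pre)
        assert np.array_equal(t1.states, t2.states)

    def test_pdl1_free_apcs_remove_priming_brake(self):
        """pdl1_apc = 0 silences the TdLN checkpoint at any drug level."""
        tb = _HillTables(ModelParams(pdl1_apc=0.0))
        for conc in [0.0, 1e-10, 1e-7]:
            assert tb.h_pd1_ln(conc) == 0.0
        assert _HillTables(ModelParams()).h_pd1_ln(0.0) > 0.1


class TestPretreatment:
    def test_stops_at_target_diameter(self):
        p = ModelParams()
        st = initialize_pretreatment(p)
        assert not st.no_tumor
        _, d = tumor_geometry(st.cancer_cells, p)
        assert p.d_init <= d <= 1.02 * p.d_init

    def test_no_growth_flags_no_tumor(self):
        st = initialize_pretreatment(ModelParams(k_growth=0.0))
        assert st.no_tumor

    def test_immune_competent_draw_controls_tumor(self):
        """High TMB with negligible checkpoint cover: the immune response
        holds the tumor below the target diameter."""
        st = initialize_pretreatment(ModelParams(
            n_clones=200.0, pdl1_cancer=300.0, pdl1_apc=1e3, q_in=2.0))
        assert st.no_tumor


class TestTreatmentDynamics:
    def test_untreated_tumor_grows_monotonically(self):
        p = ModelParams()
        pre = initialize_pretreatment(p)
        traj = simulate_patient(p, [], pre_state=pre)
        d = traj.diameter_cm
        assert np.all(np.diff(d) > -1e-9)
        assert d[-1] > 2.0 * d[0]

    def test_deterministic_repeat(self):
        p = ModelParams(n_clones=120.0, pdl1_cancer=5e4)
        pre = initialize_pretreatment(p)
        t1 = simulate_patient(p, [ATEZO, CIBA], pre_state=pre)
        t2 = simulate_patient(p, [ATEZO, CIBA], pre_state=pre)
        assert np.array_equal(t1.states, t2.states)
        assert np.array_equal(t1.conc_atezolizumab, t2.conc_atezolizumab)

    def test_solver_convergence(self):
        """Halving tolerances changes the day-400 diameter by < 0.1 %."""
        p = ModelParams(n_clones=90.0, pdl1_cancer=6e4)
        pre = initialize_pretreatment(p)
        d1 = simulate_patient(p, [ATEZO], pre_state=pre,
                              rtol=1e-6, atol=1e-3).diameter_cm[-1]
        d2 = simulate_patient(p, [ATEZO], pre_state=pre,
                              rtol=5e-7, atol=5e-4).diameter_cm[-1]
        assert abs(d2 - d1) / d1 < 1e-3

    def test_tmb_ladder_monotone(self):
        """Day-400 burden under atezolizumab is non-increasing in TMB,
        everything else fixed."""
        burdens = []
        for n in [20.0, 50.0, 84.0, 120.0, 200.0]:
            p = ModelParams(n_clones=n, pdl1_cancer=6e4, cea_total=1e3)
            pre = initialize_pretreatment(p)
            traj = simulate_patient(p, [ATEZO], pre_state=pre)
            burdens.append(traj.state("cancer_cells")[-1])
        assert all(a >= b * (1 - 1e-6) for a, b in zip(burdens, burdens[1:]))

    def test_tce_dose_response(self):
        """Day-400 burden is non-increasing in cibisatamab dose up to the
        clinical 60 mg; 240 mg sits across the trimer hook optimum, so it
        is only required not to lose ground beyond a small margin."""
        p = ModelParams(n_clones=90.0, pdl1_cancer=6e4, cea_total=2e5,
                        lam=6.0)
        pre = initialize_pretreatment(p)
        burdens = []
        for mg in [0.0, 15.0, 60.0, 240.0]:
            traj = simulate_patient(p, [Regimen("cibisatamab", mg, 7.0)],
                                    pre_state=pre)
            burdens.append(traj.state("cancer_cells")[-1])
        assert all(a >= b * (1 - 1e-6)
                   for a, b in zip(burdens[:3], burdens[1:3]))
        assert burdens[3] <= burdens[2] * 1.01
        assert burdens[3] < burdens[0]

    def test_nonnegative_states_random_draws(self):
        """States stay non-negative across random patients and all arms
        (12 fresh draws x 3 arms; the 400-VP acceptance fixture covers the
        cohort-scale sweep)."""
        from qspvct.virtual_cohort import default_parameter_space, lhs_sample

        table = lhs_sample(default_parameter_space(), 12, seed=99)
        arms = default_arms()
        for _, row in table.iterrows():
            p = ModelParams(**{k: float(v) for k, v in row.items()})
            pre = initialize_pretreatment(p)
            if pre.no_tumor:
                continue
            for arm in arms:
                traj = simulate_patient(p, arm.regimens, pre_state=pre)
                assert np.all(traj.states >= 0.0)

    def test_combination_dominance_on_cohort(self, trial400):
        """Per patient, the combination arm's day-400 percent change never
        exceeds either monotherapy's beyond solver slack (killing terms are
        additive and Hill factors are monotone in their drugs)."""
        by_arm = {arm: {r.patient_id: r.pct_change for r in recs}
                  for arm, recs in trial400.records.items()}
        common = (set(by_arm["combination"])
                  & set(by_arm["atezolizumab_mono"])
                  & set(by_arm["cibisatamab_mono"]))
        assert len(common) >= 100
        for pid in common:
            combo = by_arm["combination"][pid]
            for mono in ("atezolizumab_mono", "cibisatamab_mono"):
                assert combo <= by_arm[mono][pid] + 0.5  # pct points


def test_pretreatment_observables_fields():
    p = ModelParams()
    st = initialize_pretreatment(p)
    obs = pretreatment_observables(st, p)
    assert set(obs) == {"tumor_diameter_cm", "blood_t_density",
                        "tumor_activated_t_density", "teff_treg_ratio"}
    assert obs["tumor_diameter_cm"] == pytest.approx(p.d_init, rel=0.02)


def test_model_params_validation():
    with pytest.raises(ValueError):
        ModelParams(d_init=0.0)
    with pytest.raises(ValueError):
        ModelParams(n_clones=0.5)
    with pytest.raises(ValueError):
        ModelParams(k_growth=-0.1)
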