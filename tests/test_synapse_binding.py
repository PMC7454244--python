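"""Binding-equilibrium solvers: closed-form oracles and invariants."""

import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from qspvct.synapse_binding import (
    CheckpointInputs, HillParams, TCEInputs, hill_checkpoint, hill_tce,
    solve_checkpoint_equilibrium, solve_tce_equilibrium,
)


def two_species_quadratic(p_tot, l_tot, kd):
    """Closed-form bound complex of P + L <-> C at equilibrium."""
    s = p_tot + l_tot + kd
    return (s - math.sqrt(s * s - 4.0 * p_tot * l_tot)) / 2.0


class TestCheckpointEquilibrium:
    @pytest.mark.parametrize("p_tot,l_tot,kd", [
        (3000.0, 10000.0, 1000.0),
        (100.0, 100.0, 10.0),
        (1e5, 50.0, 2000.0),
        (500.0, 1e6, 1.0),
    ])
    def test_drug_free_matches_quadratic_oracle(self, p_tot, l_tot, kd):
        """No drug, no PD-L2: solver equals the two-species closed form."""
        cx = solve_checkpoint_equilibrium(CheckpointInputs(
            pd1_total=p_tot, pdl1_total=l_tot, kd_pd1_pdl1=kd))
        expected = two_species_quadratic(p_tot, l_tot, kd)
        assert cx.c_pd1_pdl1 == pytest.approx(expected, rel=1e-6)
        assert cx.c_pd1_pdl2 == 0.0

    def test_spec_scale_drug_free_value(self):
        """Frozen oracle value for the 3000/10000/1000 configuration."""
        cx = solve_checkpoint_equilibrium(CheckpointInputs(
            pd1_total=3000.0, pdl1_total=10000.0, kd_pd1_pdl1=1000.0))
        # ((P+L+K) - sqrt((P+L+K)^2 - 4 P L)) / 2 evaluated by hand
        assert cx.c_pd1_pdl1 == pytest.approx(2641.1010564593266, rel=1e-9)

    def test_saturating_drug_clears_pdl1_axis(self):
        """Excess anti-PD-L1 abolishes PD-1:PD-L1; PD-1:PD-L2 approaches
        the PD-L2-only closed form (the drug does not bind PD-L2)."""
        inp = CheckpointInputs(pd1_total=3000.0, pdl1_total=10000.0,
                               r_pdl2=0.05, chi=3.0)
        sat = solve_checkpoint_equilibrium(
            CheckpointInputs(pd1_total=3000.0, pdl1_total=10000.0,
                             r_pdl2=0.05, chi=3.0,
                             drug_conc=1e7 * inp.kd_drug))
        free = solve_checkpoint_equilibrium(inp)
        assert sat.c_pd1_pdl1 < 1e-3 * free.c_pd1_pdl1
        pdl2_only = two_species_quadratic(3000.0, 0.05 * 10000.0,
                                          inp.kd_pd1_pdl2)
        assert sat.c_pd1_pdl2 == pytest.approx(pdl2_only, rel=1e-3)

    def test_no_pdl1_means_no_complexes(self):
        cx = solve_checkpoint_equilibrium(CheckpointInputs(
            pd1_total=3000.0, pdl1_total=0.0, r_pdl2=0.05, drug_conc=1e-8))
        assert cx.c_pd1_pdl1 == 0.0
        assert cx.c_pd1_pdl2 == 0.0  # PD-L2 total is slaved to PD-L1
        assert cx.free_pd1 == 3000.0

    def test_mass_conservation_random_draws(self):
        """Mass balances hold to 1e-8 relative over 1000 random inputs."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            inp = CheckpointInputs(
                pd1_total=10 ** rng.uniform(1, 5),
                pdl1_total=10 ** rng.uniform(1, 6),
                r_pdl2=rng.uniform(0, 0.07),
                drug_conc=10 ** rng.uniform(-14, -5) * rng.integers(0, 2),
                chi=rng.uniform(0, 10),
                kd_pd1_pdl1=10 ** rng.uniform(2, 4),
                kd_pd1_pdl2=10 ** rng.uniform(2, 5),
            )
            cx = solve_checkpoint_equilibrium(inp)
            for v in vars(cx).values():
                assert v >= 0.0
            assert (cx.free_pd1 + cx.c_pd1_pdl1 + cx.c_pd1_pdl2
                    == pytest.approx(inp.pd1_total, rel=1e-8))
            assert (cx.free_pdl1 + cx.c_pd1_pdl1 + cx.c_drug_pdl1_mono
                    + 2 * cx.c_drug_pdl1_cross
                    == pytest.approx(inp.pdl1_total, rel=1e-8))
            if inp.pdl2_total > 0:
                assert (cx.free_pdl2 + cx.c_pd1_pdl2
                        == pytest.approx(inp.pdl2_total, rel=1e-8))

    def test_drug_competition_monotone(self):
        """More drug -> strictly less PD-1:PD-L1; more chi -> less free PD-L1."""
        base = dict(pd1_total=3000.0, pdl1_total=2e4, r_pdl2=0.03, chi=2.0)
        c1 = [solve_checkpoint_equilibrium(
            CheckpointInputs(drug_conc=c, **base)).c_pd1_pdl1
            for c in [0.0, 1e-10, 1e-9, 1e-8, 1e-7]]
        assert all(a > b for a, b in zip(c1, c1[1:]))
        free = [solve_checkpoint_equilibrium(CheckpointInputs(
            pd1_total=3000.0, pdl1_total=2e4, drug_conc=1e-9,
            chi=chi)).free_pdl1 for chi in [0.0, 1.0, 5.0, 10.0]]
        assert all(a > b for a, b in zip(free, free[1:]))

    def test_deterministic(self):
        inp = CheckpointInputs(pd1_total=4e3, pdl1_total=3e4, r_pdl2=0.04,
                               drug_conc=3e-9, chi=1.7)
        assert solve_checkpoint_equilibrium(inp) == solve_checkpoint_equilibrium(inp)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            CheckpointInputs(pd1_total=-1.0, pdl1_total=100.0)
        with pytest.raises(ValueError):
            CheckpointInputs(pd1_total=1.0, pdl1_total=1.0, r_pdl2=0.2)


class TestTCEEquilibrium:
    def test_zero_dose_no_bound_species(self):
        sp = solve_tce_equilibrium(TCEInputs(cea_total=1e5, cd3_total=5e4))
        assert sp.trimer == sp.dimer_cea == sp.dimer_cd3 == 0.0
        assert sp.free_cea == 1e5 and sp.free_cd3 == 5e4

    @pytest.mark.parametrize("conc", [1e-12, 1e-9, 1e-6])
    def test_lambda_zero_means_no_trimer(self, conc):
        sp = solve_tce_equilibrium(TCEInputs(
            cea_total=1e5, cd3_total=5e4, tce_conc=conc, lam=0.0))
        assert sp.trimer == 0.0
        assert sp.dimer_cea > 0.0  # monovalent binding persists

    def test_mass_conservation_and_trimer_bound(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            inp = TCEInputs(
                cea_total=10 ** rng.uniform(2, 6),
                cd3_total=10 ** rng.uniform(3, 6),
                tce_conc=10 ** rng.uniform(-13, -5),
                lam=rng.uniform(0, 10),
                kd_cea=10 ** rng.uniform(-9, -7),
                kd_cd3=10 ** rng.uniform(-8, -6),
            )
            sp = solve_tce_equilibrium(inp)
            assert sp.free_cea + sp.dimer_cea + sp.trimer == pytest.approx(
                inp.cea_total, rel=1e-8)
            assert sp.free_cd3 + sp.dimer_cd3 + sp.trimer == pytest.approx(
                inp.cd3_total, rel=1e-8)
            assert 0.0 <= sp.trimer <= min(inp.cea_total, inp.cd3_total)

    def test_hook_effect_unimodal_matches_bruteforce(self):
        """Dose-trimer curve is bell-shaped; peak agrees with an
        independent 2-D least-squares solve to 3 significant figures."""
        base = dict(cea_total=1e5, cd3_total=5e4, lam=3.0,
                    kd_cea=5e-9, kd_cd3=1e-7)
        doses = np.logspace(-13, -5, 81)
        trimer = np.array([solve_tce_equilibrium(
            TCEInputs(tce_conc=a, **base)).trimer for a in doses])
        # unimodal: increasing run then decreasing run
        d = np.diff(trimer)
        sign_changes = int(np.sum(np.diff(np.sign(d[d != 0.0])) != 0))
        assert sign_changes <= 1
        assert trimer[0] < 1e-3 * trimer.max()
        assert trimer[-1] < 0.5 * trimer.max()

        def brute(a):
            inp = TCEInputs(tce_conc=a, **base)
            alpha, beta = a / inp.kd_cea, a / inp.kd_cd3
            g = inp.lam * a / (inp.kd_cea * inp.kd_cd3 * inp.contact_area_scale)

            def resid(logx):
                rf, tf = np.exp(logx)
                return [rf * (1 + alpha) + g * rf * tf - inp.cea_total,
                        tf * (1 + beta) + g * rf * tf - inp.cd3_total]

            sol = least_squares(resid, x0=np.log([inp.cea_total / 2,
                                                  inp.cd3_total / 2]),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
            rf, tf = np.exp(sol.x)
            return g * rf * tf

        i_peak = int(np.argmax(trimer))
        brute_vals = np.array([brute(a) for a in doses])
        assert int(np.argmax(brute_vals)) == i_peak
        assert trimer[i_peak] == pytest.approx(brute_vals[i_peak], rel=1e-3)

    def test_deterministic(self):
        inp = TCEInputs(cea_total=2e5, cd3_total=8e4, tce_conc=3e-9, lam=4.2)
        assert solve_tce_equilibrium(inp) == solve_tce_equilibrium(inp)


class TestHillFactors:
    def test_checkpoint_trivial_points(self):
        cx0 = solve_checkpoint_equilibrium(CheckpointInputs(
            pd1_total=0.0, pdl1_total=0.0))
        assert hill_checkpoint(cx0, HillParams(k_half=100.0)) == 0.0
        # half-max: S = k_half with delta = 0, n = 1
        cx = solve_checkpoint_equilibrium(CheckpointInputs(
            pd1_total=1e8, pdl1_total=100.0, kd_pd1_pdl1=1.0))
        hp = HillParams(k_half=cx.c_pd1_pdl1, n_hill=1.0, delta=0.0)
        assert hill_checkpoint(cx, hp) == pytest.approx(0.5, rel=1e-12)

    def test_delta_zero_reduces_to_pdl1_only(self):
        """delta = 0 makes the Hill blind to any PD-1:PD-L2 complex."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            inp = CheckpointInputs(
                pd1_total=10 ** rng.uniform(3, 4.5),
                pdl1_total=10 ** rng.uniform(3, 5),
                r_pdl2=rng.uniform(0.01, 0.07))
            cx = solve_checkpoint_equilibrium(inp)
            assert cx.c_pd1_pdl2 > 0
            stripped = solve_checkpoint_equilibrium(
                CheckpointInputs(pd1_total=inp.pd1_total,
                                 pdl1_total=inp.pdl1_total, r_pdl2=0.0))
            hp0 = HillParams(k_half=500.0, n_hill=2.0, delta=0.0)
            h_with = hill_checkpoint(cx, hp0)
            # identical Hill output as a PD-L2-free system with the same
            # PD-1:PD-L1 complex density
            s = cx.c_pd1_pdl1
            expected = s ** 2 / (s ** 2 + 500.0 ** 2)
            assert h_with == pytest.approx(expected, rel=1e-12)
            assert abs(h_with - hill_checkpoint(stripped, hp0)) < 0.05

    def test_tce_trivial_and_monotone(self):
        hp = HillParams(k_half=1000.0, n_hill=2.0)
        sp0 = solve_tce_equilibrium(TCEInputs(cea_total=1e5, cd3_total=5e4))
        assert hill_tce(sp0, hp) == 0.0
        rng = np.random.default_rng(11)
        for _ in range(1000):
            hp = HillParams(k_half=10 ** rng.uniform(1, 5),
                            n_hill=rng.uniform(1, 4))
            t1, t2 = sorted(10 ** rng.uniform(0, 5, size=2))
            sp1 = solve_tce_equilibrium(TCEInputs(
                cea_total=t1, cd3_total=t1, tce_conc=1e-8, lam=5.0))
            sp2 = solve_tce_equilibrium(TCEInputs(
                cea_total=t2, cd3_total=t2, tce_conc=1e-8, lam=5.0))
            assert sp2.trimer >= sp1.trimer
            assert hill_tce(sp2, hp) >= hill_tce(sp1, hp)

    def test_hill_params_validation(self):
        with pytest.raises(ValueError):
            HillParams(k_half=0.0)
        with pytest.raises(ValueError):
            HillParams(k_half=1.0, n_hill=0.5)
        with pytest.raises(ValueError):
            HillParams(k_half=1.0, delta=1.5)
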