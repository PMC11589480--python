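"""ARF profiles, binding equilibria, promoter occupancy and simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from napdyn import nap_model, synthetic

conc = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


class TestArfProfile:
    def test_two_equal_points_give_constant_profile(self):
        prof = nap_model.fit_arf_profile([0.0, 24.0], [1.0, 1.0])
        np.testing.assert_allclose(prof(np.linspace(0, 24, 50)), 1.0)

    def test_monotone_data_give_monotone_interpolant(self):
        t = np.array([0.0, 4.0, 8.0, 12.0, 24.0])
        v = 0.02 + 0.98 * np.exp(-t / 3.0)
        prof = nap_model.fit_arf_profile(t, v)
        dense = prof(np.linspace(0, 24, 2000))
        assert (np.diff(dense) <= 1e-12).all()
        assert dense.min() >= v.min() - 1e-12  # no undershoot

    def test_knots_reproduced_exactly(self, arf_tables):
        noisy, _ = arf_tables
        profs = nap_model.fit_arf_profiles(noisy)
        for (arf, rep), prof in profs.items():
            grp = noisy[(noisy.arf == arf) & (noisy.replicate == int(rep))]
            np.testing.assert_allclose(prof(grp.time_h), grp.fc, atol=1e-12)

    def test_constant_extrapolation_beyond_last_knot(self):
        prof = nap_model.fit_arf_profile([0.0, 10.0], [1.0, 0.2])
        assert prof(50.0) == pytest.approx(prof(10.0))

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            nap_model.fit_arf_profile([0.0, 4.0, 4.0], [1.0, 0.5, 0.4])


class TestEquilibrium:
    def test_no_iaa_leaves_arf1_free(self):
        A1f, C, If = nap_model.arf1_iaa_equilibrium(2.0, 0.0, 0.5)
        assert (A1f, C, If) == (2.0, 0.0, 0.0)

    def test_tight_binding_limit_sequesters_everything(self):
        A1f, C, If = nap_model.arf1_iaa_equilibrium(1.0, 1.0, 1e-14)
        assert C == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_unit_case_quadratic_root(self):
        # root of C^2 - 3C + 1 with C <= 1: (3 - sqrt(5))/2
        _, C, _ = nap_model.arf1_iaa_equilibrium(1.0, 1.0, 1.0)
        assert C == pytest.approx((3 - np.sqrt(5)) / 2, rel=1e-12)

    @given(conc, conc, st.floats(min_value=1e-6, max_value=1e3))
    def test_mass_conservation_and_mass_action(self, A, I, K):
        A1f, C, If = nap_model.arf1_iaa_equilibrium(A, I, K)
        assert A1f >= 0 and C >= 0 and If >= 0
        np.testing.assert_allclose(A1f + C, A, atol=1e-9 * max(A, 1))
        np.testing.assert_allclose(If + C, I, atol=1e-9 * max(I, 1))
        np.testing.assert_allclose(A1f * If, K * C, atol=1e-6 * max(A * I, 1))


class TestOccupancy:
    def test_empty_promoter(self, default_params):
        assert nap_model.occupancy(0, 0, 0, default_params).phi_act == 0.0

    def test_half_saturation(self, default_params):
        p = nap_model.NAPParameters.defaults(K_1=2.0)
        assert nap_model.occupancy(2.0, 0, 0, p).phi_act == pytest.approx(0.5)

    def test_equal_competitor_partition(self):
        p = nap_model.NAPParameters.defaults(K_1=1.0, K_2=1.0)
        assert nap_model.occupancy(1.0, 0.0, 1.0, p).phi_act == pytest.approx(1 / 3)

    def test_bruteforce_matches_closed_form_all_site_counts(self, default_params):
        rng = np.random.default_rng(0)
        for n in range(1, 5):
            for _ in range(20):
                a1, ai, a2 = rng.uniform(0, 5, 3)
                closed = nap_model.occupancy(a1, ai, a2, default_params)
                brute, _ = nap_model.occupancy_bruteforce(a1, ai, a2,
                                                          default_params, n_sites=n)
                assert abs(closed.phi_act - brute.phi_act) < 1e-10
                assert abs(closed.p_A2 - brute.p_A2) < 1e-10

    def test_bruteforce_empty_state_and_symmetry(self, default_params):
        brute, micro = nap_model.occupancy_bruteforce(0, 0, 0, default_params, n_sites=2)
        assert micro[("empty", "empty")] == pytest.approx(1.0)
        sym, _ = nap_model.occupancy_bruteforce(1.5, 0.0, 1.5, default_params, n_sites=3)
        assert sym.p_A1 == pytest.approx(sym.p_A2, rel=1e-12)

    def test_bruteforce_site_cap(self, default_params):
        with pytest.raises(ValueError):
            nap_model.occupancy_bruteforce(1, 0, 1, default_params, n_sites=9)

    def test_monotonicity_in_activator_and_repressor(self, default_params):
        grid = np.linspace(0.0, 10.0, 50)
        phi_up = nap_model.occupancy(grid, 0.3, 2.0, default_params).phi_act
        assert (np.diff(phi_up) > 0).all()
        phi_down = nap_model.occupancy(1.0, 0.3, grid, default_params).phi_act
        assert (np.diff(phi_down) < 0).all()
        phi_seq = nap_model.occupancy(1.0, grid, 2.0, default_params).phi_act
        assert (np.diff(phi_seq) < 0).all()


class TestHalfLife:
    def test_no_auxin_closed_form(self):
        p = nap_model.NAPParameters.defaults(delta_I0=0.01)
        assert nap_model.iaa_effective_halflife(p, 0.0) == pytest.approx(np.log(2) / 0.01)

    def test_saturating_limit_matches_measured_turnover(self, default_params):
        from napdyn.params import load_mpiaa_decay
        hl = nap_model.iaa_effective_halflife(default_params, 1e12)
        assert hl == pytest.approx(load_mpiaa_decay()["half_life_min"], rel=1e-9)

    def test_zero_decay_is_infinite(self):
        p = nap_model.NAPParameters.defaults(delta_I0=0.0)
        assert nap_model.iaa_effective_halflife(p, 0.0) == np.inf


class TestSimulate:
    @staticmethod
    def flat_profiles(t_max: float = 500.0):
        one = nap_model.fit_arf_profile([0.0, t_max], [1.0, 1.0])
        return one, one

    def test_no_arf1_gives_basal_output(self, default_params):
        p = nap_model.NAPParameters.defaults(s1=0.0)
        res = nap_model.simulate(p, *self.flat_profiles())
        np.testing.assert_allclose(res.transcription_rate, p.basal_m, rtol=1e-9)

    def test_constant_inputs_converge_to_closed_form_steady_state(self, default_params):
        res = nap_model.simulate(default_params, *self.flat_profiles(),
                                 t_span=(0.0, 200.0))
        rate_ss = res.transcription_rate[-1]
        np.testing.assert_allclose(res.m[-1], rate_ss / default_params.delta_m,
                                   rtol=1e-6)

    def test_state_stays_nonnegative_and_finite(self, default_params, arf_tables):
        noisy, _ = arf_tables
        profs = nap_model.fit_arf_profiles(noisy)
        res = nap_model.simulate(default_params, profs[("ARF1", "1")],
                                 profs[("ARF2", "1")])
        for arr in (res.I, res.m, res.phi_act, res.transcription_rate):
            assert np.isfinite(arr).all() and (arr >= 0).all()
        assert (res.phi_act <= 1.0).all()

    def test_arf2_freeze_keeps_output_near_basal(self, default_params, arf_tables):
        """Blocking ARF2 degradation in silico abolishes the response output."""
        noisy, _ = arf_tables
        profs = nap_model.fit_arf_profiles(noisy)
        for rep in ("1", "2", "3"):
            on = nap_model.simulate(default_params, profs[("ARF1", rep)],
                                    profs[("ARF2", rep)], scenario="degradation_on")
            off = nap_model.simulate(default_params, profs[("ARF1", rep)],
                                     profs[("ARF2", rep)],
                                     scenario="arf2_degradation_off")
            assert (on.transcription_rate >= off.transcription_rate - 1e-12).all()
            r = off.transcription_rate
            assert np.ptp(r) <= 0.10 * r[0]

    def test_rising_a1_a2_ratio_raises_output(self, default_params, arf_tables):
        noisy, _ = arf_tables
        profs = nap_model.fit_arf_profiles(noisy)
        res = nap_model.simulate(default_params, profs[("ARF1", "1")],
                                 profs[("ARF2", "1")])
        assert res.transcription_rate[-1] > 1.5 * res.transcription_rate[0]

    def test_auxin_step_down_raises_steady_iaa(self, default_params):
        hi = nap_model.simulate(default_params, *self.flat_profiles(),
                                auxin=100.0, t_span=(0, 100))
        lo = nap_model.simulate(default_params, *self.flat_profiles(),
                                auxin=0.01, t_span=(0, 100))
        assert lo.I[-1] > hi.I[-1]

    def test_profile_not_covering_span_rejected(self, default_params):
        short = nap_model.fit_arf_profile([0.0, 4.0], [1.0, 0.5])
        with pytest.raises(ValueError, match="cover"):
            nap_model.simulate(default_params, short, short, t_span=(0.0, 24.0))


class TestScenarioReport:
    def test_identical_scenarios_give_unit_ratio(self, default_params):
        one = nap_model.fit_arf_profile([0.0, 24.0], [1.0, 1.0])
        a = nap_model.simulate(default_params, one, one, scenario="degradation_on")
        b = nap_model.simulate(default_params, one, one,
                               scenario="arf2_degradation_off")
        out = nap_model.scenario_report([a, b])
        np.testing.assert_allclose(out.ratio_on_off, 1.0, rtol=1e-9)

    def test_empty_input_gives_empty_table(self):
        assert nap_model.scenario_report([]).empty

    def test_grid_mismatch_rejected(self, default_params):
        one = nap_model.fit_arf_profile([0.0, 24.0], [1.0, 1.0])
        a = nap_model.simulate(default_params, one, one, n_report=100)
        b = nap_model.simulate(default_params, one, one, n_report=50,
                               scenario="arf2_degradation_off")
        with pytest.raises(ValueError, match="grid"):
            nap_model.scenario_report([a, b])
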