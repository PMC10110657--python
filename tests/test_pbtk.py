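"""Whole-body ODE system: conservation, limits, route handling."""

import numpy as np
import pytest

from retropbtk import pbtk


class TestDerivative:
    def test_zero_state_gives_zero_derivative(self, mouse_params):
        f = pbtk.build_ode_system(mouse_params)
        dy = f(0.0, np.zeros(pbtk.N_STATES))
        assert np.all(dy == 0.0)

    def test_total_mass_is_conserved_pointwise(self, mouse_params, rng):
        # body + terminal pools: the derivative of the total is zero for any
        # state (metabolite pools are bookkeeping subsets, excluded)
        f = pbtk.build_ode_system(mouse_params)
        total_idx = [pbtk.IDX[s] for s in pbtk.BODY_STATES + pbtk.SINK_STATES]
        for _ in range(20):
            y = rng.uniform(0.0, 500.0, pbtk.N_STATES)
            dy = f(0.3, y)
            assert abs(dy[total_idx].sum()) < 1e-9 * max(np.abs(dy).max(), 1.0)

    def test_compiled_and_reference_kernels_agree(self, mouse_params, rng):
        f_jit = pbtk.build_ode_system(mouse_params, jit=True)
        f_py = pbtk.build_ode_system(mouse_params, jit=False)
        f_ref = pbtk._build_ode_system_reference(mouse_params)
        for _ in range(10):
            y = rng.uniform(0.0, 1000.0, pbtk.N_STATES)
            np.testing.assert_allclose(f_jit(0.1, y), f_py(0.1, y), rtol=0,
                                       atol=0)
            np.testing.assert_allclose(f_py(0.1, y), f_ref(0.1, y), rtol=1e-12)

    def test_metabolism_saturates_at_organ_vmax(self, mouse_params):
        f = pbtk.build_ode_system(mouse_params)
        y = np.zeros(pbtk.N_STATES)
        y[pbtk.IDX["liver_c"]] = 1e12  # far above K_M
        dy = f(0.0, y)
        vmax_organ = (mouse_params.hepatic.vmax_liv
                      * mouse_params.physiology.liver_mass * 60.0)
        assert dy[pbtk.IDX["met_liv"]] == pytest.approx(vmax_organ, rel=1e-4)


class TestSimulate:
    def test_zero_dose_gives_zero_trajectories(self, mouse_params):
        res = pbtk.simulate(mouse_params, pbtk.DoseEvent("po", 0.0, 0.0), 4.0)
        assert np.all(res.states == 0.0)
        assert res.cmax_liv_vi() == 0.0

    @pytest.mark.parametrize("route", ["iv", "ip", "po"])
    @pytest.mark.parametrize("dose", [0.001, 1.0, 100.0])
    def test_mass_balance_all_routes(self, mouse_params, route, dose):
        res = pbtk.simulate(mouse_params, pbtk.DoseEvent(route, dose, 0.0), 12.0)
        assert res.mass_balance_error() < 1e-6
        assert np.all(res.states[:, -1] > -1e-6)

    def test_linearity_below_saturation(self, rat_params):
        lo = pbtk.simulate(rat_params, pbtk.DoseEvent("po", 0.001, 0.0), 12.0)
        hi = pbtk.simulate(rat_params, pbtk.DoseEvent("po", 0.002, 0.0), 12.0)
        mask = lo.states.max(axis=1) > 1e-8 * lo.administered
        ratio = hi.states[mask][:, 1:] / np.maximum(lo.states[mask][:, 1:], 1e-300)
        sel = lo.states[mask][:, 1:] > 1e-6 * lo.administered
        assert np.allclose(ratio[sel], 2.0, rtol=1e-3)

    def test_iv_cmax_at_first_grid_point_after_dose(self, mouse_params):
        res = pbtk.simulate(mouse_params, pbtk.DoseEvent("iv", 1.0, 0.0), 6.0)
        plasma = res.states[pbtk.IDX["plasma"]]
        assert np.argmax(plasma) == 0  # bolus appears at t=0 on the grid

    def test_cmax_monotone_in_dose(self, mouse_params):
        cmax = [pbtk.simulate(mouse_params, pbtk.DoseEvent("po", d, 0.0),
                              24.0).cmax_liv_vi()
                for d in (0.1, 0.5, 2.0, 10.0, 50.0)]
        assert np.all(np.diff(cmax) > 0)

    def test_integrator_tolerance_independence(self, mouse_params):
        a = pbtk.simulate(mouse_params, pbtk.DoseEvent("po", 1.0, 0.0), 24.0,
                          rtol=1e-8, atol=1e-10).cmax_liv_vi()
        b = pbtk.simulate(mouse_params, pbtk.DoseEvent("po", 1.0, 0.0), 24.0,
                          rtol=5e-9, atol=5e-11).cmax_liv_vi()
        assert a == pytest.approx(b, rel=1e-4)

    def test_unabsorbed_fraction_routed_to_sink(self, mouse_params):
        res = pbtk.simulate(mouse_params, pbtk.DoseEvent("po", 1.0, 0.0), 2.0)
        frac = res.states[pbtk.IDX["unabsorbed"], -1] / res.administered
        assert frac == pytest.approx(1.0 - mouse_params.absorption.f_a,
                                     rel=1e-9)

    def test_t_end_before_dose_rejected(self, mouse_params):
        with pytest.raises(ValueError):
            pbtk.simulate(mouse_params, pbtk.DoseEvent("iv", 1.0, 5.0), 4.0)

    def test_multiple_dose_events_accumulate(self, mouse_params):
        res = pbtk.simulate(mouse_params,
                            [pbtk.DoseEvent("iv", 1.0, 0.0),
                             pbtk.DoseEvent("iv", 1.0, 2.0)], 8.0)
        single = pbtk.simulate(mouse_params, pbtk.DoseEvent("iv", 1.0, 0.0), 8.0)
        assert res.administered == pytest.approx(2 * single.administered)
        assert res.mass_balance_error() < 1e-6


class TestMetaboliteKinetics:
    def test_dna_adduct_late_phase_slope_is_lambda2(self, mouse_params):
        # after an i.p. bolus the DNA-adduct pool decays biexponentially;
        # the fitted terminal slope equals the slow-phase rate constant
        res = pbtk.simulate(mouse_params, pbtk.DoseEvent("ip", 35.0, 0.0),
                            2000.0, n_points=2000)
        dna = (res.states[pbtk.IDX["dhr_dna_fast"]]
               + res.states[pbtk.IDX["dhr_dna_slow"]])
        t = res.time_grid
        late = t > 1200.0
        slope = np.polyfit(t[late], np.log(dna[late]), 1)[0]
        lam2 = mouse_params.metabolites.lambda2_dhr_dna
        assert -slope == pytest.approx(lam2, rel=0.02)

    def test_metabolite_pools_bounded_by_formed_metabolites(self, mouse_params):
        res = pbtk.simulate(mouse_params, pbtk.DoseEvent("ip", 35.0, 0.0), 48.0)
        pools = res.states[[pbtk.IDX[s] for s in
                            ("dhr_gsh", "dhr_prot", "dhr_dna_fast",
                             "dhr_dna_slow")]].sum(axis=0)
        assert np.all(pools <= res.states[pbtk.IDX["met_liv"]] * (1 + 1e-9))


class TestDisposition:
    def test_shares_sum_to_one(self, rat_params):
        res = pbtk.simulate(rat_params, pbtk.DoseEvent("po", 1.0, 0.0), 24.0)
        s = pbtk.disposition_summary(res)
        shares = (s["met_liv_share_of_eliminated"]
                  + s["met_gut_share_of_eliminated"]
                  + s["urine_share_of_eliminated"]
                  + s["bile_share_of_eliminated"])
        assert shares == pytest.approx(1.0, abs=1e-4)
        assert s["balance"] == pytest.approx(1.0, abs=1e-6)
        assert not s["censored"]

    def test_incomplete_run_is_flagged_censored(self, rat_params):
        res = pbtk.simulate(rat_params, pbtk.DoseEvent("po", 1.0, 0.0), 0.5)
        assert pbtk.disposition_summary(res)["censored"]
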