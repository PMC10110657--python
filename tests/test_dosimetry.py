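"""Cytotoxicity fitting, reverse dosimetry and BMD machinery."""

import numpy as np
import pandas as pd
import pytest

from retropbtk import dosimetry, pbtk, synthetic


class TestSigmoidFit:
    def test_noiseless_exact_recovery(self):
        data = synthetic.generate_cytotox(150.0, 2.0, cv=0.0, seed=0)
        fit = dosimetry.fit_sigmoid_ic50(data)
        assert fit.ic50 == pytest.approx(150.0, rel=1e-6)
        assert fit.slope == pytest.approx(2.0, rel=1e-6)

    def test_agrees_with_dense_grid_search(self):
        data = synthetic.generate_cytotox(150.0, 2.0, cv=0.08, seed=4)
        fit = dosimetry.fit_sigmoid_ic50(data)
        c = data.frame["concentration_uM"].to_numpy()
        v = data.frame["viability"].to_numpy()
        grid_ic50 = np.geomspace(50, 400, 300)
        grid_slope = np.linspace(0.5, 5.0, 150)
        best = None
        for ic in grid_ic50:
            pred = 1.0 / (1.0 + np.power(c[:, None] / ic, grid_slope[None, :]))
            rss = ((pred - v[:, None]) ** 2).sum(axis=0)
            j = int(np.argmin(rss))
            if best is None or rss[j] < best[0]:
                best = (rss[j], ic, grid_slope[j])
        assert fit.ic50 == pytest.approx(best[1], rel=5e-3)
        assert fit.slope == pytest.approx(best[2], rel=2e-2)

    def test_flat_response_flags_unbounded_ic50(self):
        frame = pd.DataFrame({"replicate_id": ["a"] * 5,
                              "concentration_uM": [0.0, 10.0, 50.0, 200.0, 800.0],
                              "viability": [1.0, 1.01, 0.99, 1.0, 0.98]})
        with pytest.warns(UserWarning):
            fit = dosimetry.fit_sigmoid_ic50(
                dosimetry.CytotoxDataset("rat", frame))
        assert not fit.identified and np.isinf(fit.ic50)


class TestConcentrationToDose:
    def test_zero_concentration_maps_to_zero_dose(self, mouse_params):
        assert dosimetry.concentration_to_dose(0.0, mouse_params) == 0.0

    def test_unreachable_target_reports_cap(self, mouse_params):
        with pytest.raises(ValueError, match="dose cap"):
            dosimetry.concentration_to_dose(1e9, mouse_params, dose_cap=100.0)

    def test_strictly_increasing_in_concentration(self, mouse_params):
        curve = dosimetry.dose_cmax_curve(mouse_params, "po", n=15)
        concs = np.geomspace(0.05, 50.0, 12)
        fup = mouse_params.compound.fup
        from scipy.optimize import brentq
        doses = [np.exp(brentq(lambda x: curve(x) - np.log(c / fup),
                               curve.x[0], curve.x[-1])) for c in concs]
        assert np.all(np.diff(doses) > 0)


class TestTranslateDoseResponse:
    def test_controls_stay_at_dose_zero(self, rat_params):
        data = synthetic.generate_cytotox(153.0, 2.5, "rat", cv=0.0, seed=1)
        curve = dosimetry.dose_cmax_curve(rat_params, "po", n=12)
        dr = dosimetry.translate_to_dose_response(data, rat_params, curve=curve)
        controls = dr[dr["dose"] == 0.0]
        assert len(controls) == 3  # one per biological replicate
        assert np.allclose(controls["response"], 100.0)
        assert np.all(dr["dose"] >= 0)


def linear_frame(noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0])
    y = 100.0 - x + noise * rng.standard_normal(x.size)
    return pd.DataFrame({"dose": x, "response": y})


class TestBmdModelAveraging:
    def test_linear_data_recovers_analytic_crossing(self):
        # response 100 - d crosses the 5% benchmark exactly at d = 5
        res = dosimetry.bmd_model_averaging(linear_frame(), bmr=0.05,
                                            n_boot=50, seed=1)
        assert res.bmd == pytest.approx(5.0, rel=0.005)
        # noise-free data: the interval collapses onto the estimate (width
        # limited only by the suite's representation of an exact line)
        assert res.bmdl <= res.bmd <= res.bmdu
        assert (res.bmdu - res.bmdl) <= 0.01 * res.bmd
        assert res.bmdl == pytest.approx(5.0, rel=0.005)
        assert res.bmdu == pytest.approx(5.0, rel=0.005)

    def test_single_model_suite_matches_its_own_bmd(self):
        frame = linear_frame(noise=0.8, seed=3)
        res = dosimetry.bmd_model_averaging(frame, bmr=0.05, n_boot=40,
                                            seed=2, models=("exp3",))
        single = [v for k, v in res.per_model_bmd.items() if k == "exp3"]
        # averaging over one model (normal-error branch dominant) stays
        # within 1% of that model's own benchmark dose
        weights = {k: v for k, v in res.weights.items()}
        dominant = max(weights, key=weights.get)
        assert res.bmd == pytest.approx(res.per_model_bmd[dominant],
                                        rel=0.01 + 1 - weights[dominant])
        assert single

    def test_interval_brackets_central_estimate(self):
        res = dosimetry.bmd_model_averaging(linear_frame(noise=1.5, seed=5),
                                            bmr=0.05, n_boot=80, seed=4)
        assert res.bmdl <= res.bmdu
        assert res.bmdl <= res.bmd * 1.05
        assert res.bmdu >= res.bmd * 0.95

    def test_too_few_doses_rejected(self):
        frame = pd.DataFrame({"dose": [0, 1, 2, 3], "response": [100, 99, 98, 97]})
        with pytest.raises(ValueError):
            dosimetry.bmd_model_averaging(frame, n_boot=10, seed=0)
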