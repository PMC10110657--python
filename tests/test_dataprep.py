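"""Unit standardization and summary de-aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retropbtk.dataprep import (KineticDataset, KineticObservation,
                                UnsupportedUnitError, deaggregate_summary,
                                standardize_units)


def obs(**overrides):
    base = dict(study_id="s1", species_id="mouse", matrix="plasma",
                route="iv", dose=5.0, time=1.0, value=10.0, unit="nmol")
    base.update(overrides)
    return KineticObservation(**base)


class TestStandardizeUnits:
    def test_nmol_identity(self, mouse_params):
        out = standardize_units(obs(), mouse_params.compound,
                                mouse_params.physiology)
        assert out.value == 10.0
        assert out.conversion == ("identity",)

    def test_ug_per_ml_dimensional_oracle(self, mouse_params):
        # 1 µg/mL * V_plasma mL / 351.44 g/mol * 1000 nmol/µmol
        out = standardize_units(obs(value=1.0, unit="ug_per_ml"),
                                mouse_params.compound, mouse_params.physiology)
        v = mouse_params.physiology.tissue_volumes["plasma"]
        assert out.value == pytest.approx(1.0 / 351.44 * 1000.0 * v, rel=1e-12)
        assert out.unit == "nmol"

    def test_ng_per_g_uses_organ_mass(self, mouse_params):
        out = standardize_units(obs(matrix="liver", value=100.0, unit="ng_per_g"),
                                mouse_params.compound, mouse_params.physiology)
        mass = mouse_params.physiology.liver_mass
        assert out.value == pytest.approx(100.0 * mass / 351.44, rel=1e-12)

    def test_percent_dose(self, mouse_params):
        out = standardize_units(obs(unit="percent_dose", value=10.0),
                                mouse_params.compound, mouse_params.physiology)
        dose_nmol = 5.0 * 0.025 / 351.44 * 1e6
        assert out.value == pytest.approx(dose_nmol * 0.10, rel=1e-12)

    def test_peak_area_ratio_passes_through_flagged(self, mouse_params):
        out = standardize_units(obs(matrix="dhr_gsh", unit="peak_area_ratio",
                                    value=3.5),
                                mouse_params.compound, mouse_params.physiology)
        assert out.relative and out.value == 3.5

    def test_unsupported_unit_is_loud(self, mouse_params):
        with pytest.raises(UnsupportedUnitError):
            standardize_units(obs(unit="furlongs"), mouse_params.compound,
                              mouse_params.physiology)

    def test_roundtrip_inversion(self, mouse_params):
        # standardize then invert through the logged factor
        raw = obs(value=2.5, unit="ug_per_ml")
        out = standardize_units(raw, mouse_params.compound,
                                mouse_params.physiology)
        factor = out.value / raw.value
        assert out.value / factor == pytest.approx(raw.value, rel=1e-12)


class TestDeaggregation:
    def test_zero_sd_replicates_the_mean(self):
        assert list(deaggregate_summary(5.0, 0.0, 3, seed=1)) == [5.0, 5.0, 5.0]

    @given(st.floats(min_value=0.5, max_value=1e4),
           st.floats(min_value=0.0, max_value=0.3),
           st.integers(min_value=2, max_value=12),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_moments_match_exactly(self, mean, cv, n, seed):
        sd = cv * mean
        x = deaggregate_summary(mean, sd, n, seed)
        assert x.mean() == pytest.approx(mean, rel=1e-12)
        if sd > 0:
            assert x.std(ddof=1) == pytest.approx(sd, rel=1e-9)
        assert np.all(x >= 0.0)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            deaggregate_summary(5.0, 1.0, 1, seed=0)

    def test_reproducible_under_seed(self):
        a = deaggregate_summary(10.0, 3.0, 5, seed=7)
        b = deaggregate_summary(10.0, 3.0, 5, seed=7)
        np.testing.assert_array_equal(a, b)


class TestKineticDataset:
    def test_expand_summaries_matches_animal_counts(self, synthetic_dataset):
        expanded = synthetic_dataset.expand_summaries(seed=3)
        for o in synthetic_dataset.observations:
            if o.n > 1:
                twins = [e for e in expanded.observations
                         if (e.study_id, e.matrix, e.time) ==
                         (o.study_id, o.matrix, o.time)]
                assert len(twins) == o.n
                values = np.array([e.value for e in twins])
                assert values.mean() == pytest.approx(o.value, rel=1e-9)

    def test_training_filter_drops_evaluation_and_relative(self, mouse_params):
        records = [
            obs(), obs(function="evaluation"),
            standardize_units(obs(matrix="dhr_gsh", unit="peak_area_ratio"),
                              mouse_params.compound, mouse_params.physiology),
        ]
        ds = KineticDataset([standardize_units(r, mouse_params.compound,
                                               mouse_params.physiology)
                             if not r.relative else r for r in records])
        assert len(ds.training().observations) == 1

    def test_frame_carries_conversion_trace(self, synthetic_dataset):
        frame = synthetic_dataset.to_frame()
        assert "conversion" in frame.columns
        assert len(frame) == len(synthetic_dataset.observations)
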