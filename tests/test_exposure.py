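import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from meatcost.exceptions import EmptyInputError, InvalidParameterError
from meatcost.exposure import (
    DEFAULT_SCHEMES,
    PROCESSED_MEAT_SCHEME,
    RED_MEAT_SCHEME,
    ExposureCategoryScheme,
    apply_cap,
    apply_serving_reduction,
    categorize,
    scenario_prevalences,
    weighted_median,
)


class TestSchemes:
    def test_red_band_assignment_at_boundaries(self):
        values = np.array([0.0, 69.9, 70.0, 139.9, 140.0, 210.0, 279.9, 280.0, 500.0])
        expected = [0, 0, 1, 1, 2, 3, 3, 4, 4]
        assert RED_MEAT_SCHEME.assign(values).tolist() == expected

    def test_processed_zero_band_is_its_own_category(self):
        values = np.array([0.0, 0.01, 49.9, 50.0, 99.9, 100.0, 150.0, 400.0])
        expected = [0, 1, 1, 2, 2, 3, 4, 4]
        assert PROCESSED_MEAT_SCHEME.assign(values).tolist() == expected

    def test_boundaries_must_increase(self):
        with pytest.raises(InvalidParameterError):
            ExposureCategoryScheme("red_meat", (70.0, 70.0, 140.0))

    def test_medians_must_lie_in_their_band(self):
        with pytest.raises(InvalidParameterError):
            ExposureCategoryScheme(
                "red_meat", (70.0, 140.0), medians=(30.0, 150.0, 200.0)
            )

    def test_negative_consumption_rejected(self):
        with pytest.raises(InvalidParameterError):
            RED_MEAT_SCHEME.assign(np.array([-1.0]))


class TestCategorize:
    def test_all_zero_processed_is_degenerate_reference(self):
        records = pd.DataFrame(
            {"red_g_day": [10.0] * 5, "processed_g_day": [0.0] * 5, "weight": 1.0}
        )
        pv = categorize(records, PROCESSED_MEAT_SCHEME)
        assert pv.p.tolist() == [1.0, 0.0, 0.0, 0.0, 0.0]

    def test_hand_counted_red_prevalence(self, red_records):
        pv = categorize(red_records, RED_MEAT_SCHEME)
        assert pv.p.tolist() == [0.25, 0.5, 0.0, 0.0, 0.25]
        assert pv.medians[0] == 30.0
        assert pv.medians[1] == 100.0
        assert pv.n_effective == 4.0

    def test_weights_shift_prevalence(self, red_records):
        weighted = red_records.assign(weight=[3.0, 0.5, 0.5, 0.0001])
        pv = categorize(weighted, RED_MEAT_SCHEME)
        assert pv.p[0] == pytest.approx(3.0 / 4.0001)
        assert pv.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_records_raise(self):
        with pytest.raises(EmptyInputError):
            categorize(pd.DataFrame(columns=["red_g_day", "processed_g_day"]), RED_MEAT_SCHEME)


def test_weighted_median_respects_weights():
    assert weighted_median(np.array([1.0, 2.0, 10.0]), np.array([1.0, 1.0, 5.0])) == 10.0
    assert weighted_median(np.array([1.0, 2.0, 10.0]), np.array([1.0, 1.0, 1.0])) == 2.0


class TestServingReduction:
    def test_weekly_reduction_spread_over_days_and_floored(self, red_records):
        out = apply_serving_reduction(red_records, red_reduction_g_week=120.0)
        assert out["red_g_day"].tolist() == pytest.approx(
            [30 - 120 / 7, 100 - 120 / 7, 100 - 120 / 7, 300 - 120 / 7]
        )
        zero = red_records.assign(red_g_day=0.0)
        assert apply_serving_reduction(zero, 120.0)["red_g_day"].eq(0.0).all()

    def test_zero_reduction_is_identity(self, red_records):
        out = apply_serving_reduction(red_records, 0.0, 0.0)
        pd.testing.assert_frame_equal(out, red_records)

    def test_negative_reduction_rejected(self, red_records):
        with pytest.raises(InvalidParameterError):
            apply_serving_reduction(red_records, -1.0)

    def test_input_frame_untouched(self, red_records):
        before = red_records.copy()
        apply_serving_reduction(red_records, 120.0, 50.0)
        pd.testing.assert_frame_equal(red_records, before)


class TestCap:
    def test_records_below_cap_unchanged(self, red_records):
        below = red_records.assign(red_g_day=[10.0, 20.0, 30.0, 40.0])
        out = apply_cap(below, "red_meat", 140.0, RED_MEAT_SCHEME)
        pd.testing.assert_frame_equal(out, below)

    def test_supra_cap_records_move_to_band_below(self, red_records):
        out = apply_cap(red_records, "red_meat", 280.0, RED_MEAT_SCHEME)
        # the 300 g/day person joins band [210, 280); that band is empty,
        # so the scheme falls back to the band midpoint
        assert out.loc[3, "red_g_day"] == 245.0
        pv = categorize(out, RED_MEAT_SCHEME)
        assert pv.p[4] == 0.0

    def test_cap_uses_empirical_median_of_target_band(self, red_records):
        out = apply_cap(red_records, "red_meat", 140.0, RED_MEAT_SCHEME)
        # band [70, 140) holds two people at 100 g/day; the capped person joins them
        assert out.loc[3, "red_g_day"] == 100.0
        pv = categorize(out, RED_MEAT_SCHEME)
        assert pv.p[2:].sum() == 0.0

    def test_cap_must_be_a_scheme_boundary(self, red_records):
        with pytest.raises(InvalidParameterError):
            apply_cap(red_records, "red_meat", 100.0, RED_MEAT_SCHEME)

    def test_cap_is_idempotent(self, survey_records):
        once = apply_cap(survey_records, "red_meat", 210.0, RED_MEAT_SCHEME)
        twice = apply_cap(once, "red_meat", 210.0, RED_MEAT_SCHEME)
        pd.testing.assert_frame_equal(once, twice)

    def test_stricter_cap_is_stochastically_dominated(self, survey_records):
        tight = categorize(
            apply_cap(survey_records, "red_meat", 140.0, RED_MEAT_SCHEME),
            RED_MEAT_SCHEME,
        )
        loose = categorize(
            apply_cap(survey_records, "red_meat", 280.0, RED_MEAT_SCHEME),
            RED_MEAT_SCHEME,
        )
        assert np.all(np.cumsum(tight.p) >= np.cumsum(loose.p) - 1e-12)


class TestScenarios:
    def test_unknown_scenario_rejected(self, survey_records):
        with pytest.raises(InvalidParameterError):
            scenario_prevalences(survey_records, 5)

    def test_cap_scenario_empties_bands_at_and_above_cap(self, survey_records):
        pairs = scenario_prevalences(survey_records, 2)
        _, red_cf = pairs["red_meat"]
        assert red_cf.p[2:].sum() == 0.0  # no mass at >= 140 g/day
        _, proc_cf = pairs["processed_meat"]
        assert proc_cf.p[2:].sum() == 0.0  # no mass at >= 50 g/day

    def test_mass_and_record_count_conserved(self, survey_records):
        for scenario in (1, 2, 3, 4):
            for p, p_cf in scenario_prevalences(survey_records, scenario).values():
                assert p.p.sum() == pytest.approx(1.0, abs=1e-9)
                assert p_cf.p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scenario_one_matches_brute_force_recount(self, survey_records):
        """Independent per-record loop over the serving-reduction transform."""
        records = survey_records.head(1000)
        pairs = scenario_prevalences(records, 1)
        for exposure, reduction in (("red_meat", 120.0), ("processed_meat", 50.0)):
            scheme = DEFAULT_SCHEMES[exposure]
            col = "red_g_day" if exposure == "red_meat" else "processed_g_day"
            counts = np.zeros(scheme.n_categories)
            for value in records[col]:
                v = max(0.0, value - reduction / 7.0)
                idx = 0
                if scheme.zero_band:
                    if v > 0:
                        idx = 1 + int(np.sum(v >= np.asarray(scheme.boundaries)))
                else:
                    idx = int(np.sum(v >= np.asarray(scheme.boundaries)))
                counts[idx] += 1
            np.testing.assert_allclose(
                pairs[exposure][1].p, counts / counts.sum(), atol=1e-12
            )


@given(
    values=st.lists(st.floats(0.0, 500.0), min_size=1, max_size=40),
    scenario=st.sampled_from([1, 2, 3, 4]),
)
def test_any_scenario_preserves_probability_mass(values, scenario):
    records = pd.DataFrame(
        {
            "red_g_day": values,
            "processed_g_day": values[::-1],
            "weight": 1.0,
        }
    )
    for p, p_cf in scenario_prevalences(records, scenario).values():
        assert abs(p.p.sum() - 1.0) < 1e-9
        assert abs(p_cf.p.sum() - 1.0) < 1e-9
        assert p.n_categories == p_cf.n_categories
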