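"""Unit and property tests for trajectory validation and QALY integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qoli import (
    Extension,
    Integration,
    QalyConfig,
    QalyResult,
    Timepoint,
    UtilityObservation,
    ValidationError,
    build_trajectory,
    compute_actual_qaly,
    compute_lost_qaly,
    compute_qaly_result,
    compute_theoretical_qaly,
)

from conftest import (
    grid_qaly_oracle,
    make_trajectory,
    random_complete_trajectory,
    step_qaly_oracle,
)

CFG = QalyConfig()


class TestUtilityObservation:
    def test_valid(self):
        obs = UtilityObservation("p1", Timepoint.PRE_SURGERY, 90, 0.55)
        assert obs.utility == 0.55

    def test_baseline_day_must_be_zero(self):
        with pytest.raises(ValidationError, match="day 0"):
            UtilityObservation("p1", Timepoint.BASELINE, 5, 0.8)

    def test_negative_day_rejected(self):
        with pytest.raises(ValidationError, match="non-negative"):
            UtilityObservation("p1", Timepoint.PRE_SURGERY, -3, 0.8)

    def test_out_of_range_utility_names_bound(self):
        with pytest.raises(ValidationError, match="1.0"):
            UtilityObservation("p1", Timepoint.PRE_SURGERY, 90, 1.05)
        with pytest.raises(ValidationError, match=r"-0.022"):
            UtilityObservation("p1", Timepoint.PRE_SURGERY, 90, -0.5)

    def test_sub_tolerance_overshoot_clamped(self):
        obs = UtilityObservation("p1", Timepoint.PRE_SURGERY, 90, 1.0 + 1e-10)
        assert obs.utility == 1.0


class TestBuildTrajectory:
    def test_three_valid_rows_sorted_complete(self):
        rows = [
            UtilityObservation("p1", Timepoint.POST_SURGERY, 150, 0.7),
            UtilityObservation("p1", Timepoint.BASELINE, 0, 0.8),
            UtilityObservation("p1", Timepoint.PRE_SURGERY, 90, 0.55),
        ]
        t = build_trajectory(rows)
        assert t.days == (0, 90, 150)
        assert t.complete

    def test_missing_pre_surgery_incomplete(self):
        rows = [
            UtilityObservation("p1", Timepoint.BASELINE, 0, 0.8),
            UtilityObservation("p1", Timepoint.POST_SURGERY, 150, 0.7),
        ]
        assert not build_trajectory(rows).complete

    def test_duplicate_timepoint_rejected(self):
        rows = [
            UtilityObservation("p1", Timepoint.BASELINE, 0, 0.8),
            UtilityObservation("p1", Timepoint.PRE_SURGERY, 90, 0.55),
            UtilityObservation("p1", Timepoint.PRE_SURGERY, 95, 0.60),
        ]
        with pytest.raises(ValidationError, match="duplicate"):
            build_trajectory(rows)

    def test_mixed_patient_ids_rejected(self):
        rows = [
            UtilityObservation("p1", Timepoint.BASELINE, 0, 0.8),
            UtilityObservation("p2", Timepoint.PRE_SURGERY, 90, 0.55),
        ]
        with pytest.raises(ValidationError, match="multiple patient ids"):
            build_trajectory(rows)

    def test_missing_baseline_rejected(self):
        rows = [UtilityObservation("p1", Timepoint.PRE_SURGERY, 90, 0.55)]
        with pytest.raises(ValidationError, match="baseline"):
            build_trajectory(rows)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            build_trajectory([])


class TestActualQaly:
    def test_constant_utility(self):
        t = make_trajectory((0, 90, 150), (0.6, 0.6, 0.6))
        assert compute_actual_qaly(t, CFG) == pytest.approx(0.3, abs=1e-12)

    def test_worked_example_against_oracle(self):
        # (0.80, 0.55, 0.70) at days (0, 90, 150), 0.5-yr window, LOCF tail
        days, utils = (0, 90, 150), (0.80, 0.55, 0.70)
        oracle = grid_qaly_oracle(days, utils)
        # closed form: (.675*90 + .625*60 + .70*32.625) / 365.25
        assert oracle == pytest.approx(121.0875 / 365.25, abs=1e-9)
        t = make_trajectory(days, utils)
        actual = compute_actual_qaly(t, CFG)
        assert actual == pytest.approx(oracle, abs=1e-8)
        assert actual == pytest.approx(0.3315195071868583, abs=1e-12)

    def test_maximum_utility(self):
        t = make_trajectory((0, 90, 150), (1.0, 1.0, 1.0))
        assert compute_actual_qaly(t, CFG) == pytest.approx(0.5, abs=1e-12)

    def test_incomplete_rejected(self):
        rows = [UtilityObservation("p1", Timepoint.BASELINE, 0, 0.8)]
        with pytest.raises(ValidationError, match="incomplete"):
            compute_actual_qaly(build_trajectory(rows), CFG)

    def test_observation_beyond_window_rejected(self):
        t = make_trajectory((0, 90, 200), (0.8, 0.6, 0.7))
        with pytest.raises(ValidationError, match="beyond"):
            compute_actual_qaly(t, CFG)

    def test_step_locf_against_midpoint_oracle(self):
        cfg = QalyConfig(integration=Integration.STEP_LOCF)
        days, utils = (0, 90, 150), (0.80, 0.55, 0.70)
        t = make_trajectory(days, utils)
        oracle = step_qaly_oracle(days, utils)
        assert compute_actual_qaly(t, cfg) == pytest.approx(oracle, abs=1e-5)

    def test_truncate_stops_at_last_observation(self):
        cfg = QalyConfig(extension=Extension.TRUNCATE)
        days, utils = (0, 90, 150), (0.80, 0.55, 0.70)
        t = make_trajectory(days, utils)
        oracle = grid_qaly_oracle(days, utils, extension="truncate")
        assert compute_actual_qaly(t, cfg) == pytest.approx(oracle, abs=1e-8)

    def test_oracle_equivalence_random(self, rng):
        for _ in range(50):
            t = random_complete_trajectory(rng)
            oracle = grid_qaly_oracle(t.days, t.utilities)
            assert compute_actual_qaly(t, CFG) == pytest.approx(oracle, abs=1e-8)


class TestTheoreticalQaly:
    @pytest.mark.parametrize(
        "u,expected", [(1.0, 0.5), (0.80, 0.40), (0.0, 0.0)]
    )
    def test_product(self, u, expected):
        assert compute_theoretical_qaly(u, CFG) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            compute_theoretical_qaly(1.2, CFG)


class TestLostQaly:
    def test_worked_example(self):
        assert compute_lost_qaly(0.40, 0.3315195071868583) == pytest.approx(
            0.0684804928131417, abs=1e-12
        )

    def test_no_change_is_zero(self):
        assert compute_lost_qaly(0.4, 0.4) == 0.0

    def test_gain_is_negative(self):
        assert compute_lost_qaly(0.3, 0.35) < 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            compute_lost_qaly(float("nan"), 0.3)


class TestQalyResult:
    def test_inconsistent_lost_rejected(self):
        with pytest.raises(ValidationError):
            QalyResult("p1", actual_qaly=0.3, theoretical_qaly=0.4, lost_qaly=0.2)

    def test_compute_qaly_result_consistency(self):
        t = make_trajectory((0, 90, 150), (0.80, 0.55, 0.70))
        r = compute_qaly_result(t, CFG)
        assert r.lost_qaly == pytest.approx(
            r.theoretical_qaly - r.actual_qaly, abs=1e-12
        )
        assert r.theoretical_qaly == pytest.approx(
            t.baseline_utility * CFG.window_years, abs=1e-12
        )


# ---------------------------------------------------------------------------
# properties

utility_st = st.floats(min_value=-0.022, max_value=1.0, allow_nan=False)


@given(u=utility_st, d1=st.integers(1, 120), d2=st.integers(121, 182))
def test_constant_trajectory_loses_nothing(u, d1, d2):
    t = make_trajectory((0, d1, d2), (u, u, u))
    r = compute_qaly_result(t, CFG)
    assert abs(r.lost_qaly) <= 1e-12


@given(
    us=st.tuples(utility_st, utility_st, utility_st),
    deltas=st.tuples(
        st.floats(0, 0.3, allow_nan=False),
        st.floats(0, 0.3, allow_nan=False),
        st.floats(0, 0.3, allow_nan=False),
    ),
    d1=st.integers(1, 120),
    d2=st.integers(121, 182),
)
def test_pointwise_lower_trajectory_not_larger_actual(us, deltas, d1, d2):
    lower = tuple(max(u - d, -0.022) for u, d in zip(us, deltas))
    a_hi = compute_actual_qaly(make_trajectory((0, d1, d2), us), CFG)
    a_lo = compute_actual_qaly(make_trajectory((0, d1, d2), lower), CFG)
    assert a_lo <= a_hi + 1e-12


@given(
    u0=utility_st,
    us=st.tuples(utility_st, utility_st),
    deltas=st.tuples(
        st.floats(0, 0.3, allow_nan=False), st.floats(0, 0.3, allow_nan=False)
    ),
    d1=st.integers(1, 120),
    d2=st.integers(121, 182),
)
def test_lowering_post_baseline_utilities_raises_lost_qaly(u0, us, deltas, d1, d2):
    # baseline held fixed so the theoretical QALY is unchanged
    lower = tuple(max(u - d, -0.022) for u, d in zip(us, deltas))
    r_hi = compute_qaly_result(make_trajectory((0, d1, d2), (u0, *us)), CFG)
    r_lo = compute_qaly_result(make_trajectory((0, d1, d2), (u0, *lower)), CFG)
    assert r_lo.lost_qaly >= r_hi.lost_qaly - 1e-12


@given(u=utility_st, d1=st.integers(1, 120), d2=st.integers(121, 182))
def test_doubling_window_doubles_constant_qalys(u, d1, d2):
    t = make_trajectory((0, d1, d2), (u, u, u))
    r1 = compute_qaly_result(t, QalyConfig(window_years=0.5))
    r2 = compute_qaly_result(t, QalyConfig(window_years=1.0))
    assert r2.actual_qaly == pytest.approx(2 * r1.actual_qaly, abs=1e-12)
    assert r2.theoretical_qaly == pytest.approx(2 * r1.theoretical_qaly, abs=1e-12)
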