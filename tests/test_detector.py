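import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import weightband as wb
from weightband.detector import mad_narrowing

from conftest import make_constant_drop_course


def brute_force_rolling(values, window):
    """Independent oracle: re-slice and recompute with the textbook formulas."""
    out = {}
    for d in range(window, len(values)):
        chunk = values[d - window : d]
        out[d] = (statistics.mean(chunk), statistics.stdev(chunk))
    return out


class TestNormalizeCourse:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            ((250.0, 255.0, 245.0), (100.0, 102.0, 98.0)),
            ((300.0,) * 5, (100.0,) * 5),
            ((200.0, 160.0), (100.0, 80.0)),
        ],
    )
    def test_percent_of_first_measurement(self, weights, expected):
        course = wb.WeightCourse("r1", tuple(range(len(weights))), weights)
        ncourse = wb.normalize_course(course)
        assert ncourse.weight_pct == pytest.approx(expected)
        assert ncourse.weight_pct[0] == 100.0

    def test_non_positive_baseline_rejected(self):
        course = wb.WeightCourse("r1", (0, 1), (0.0, 10.0))
        with pytest.raises(wb.ValidationError, match="baseline"):
            wb.normalize_course(course)

    def test_other_fields_copied(self, simple_course):
        ncourse = wb.normalize_course(simple_course)
        assert ncourse.days == simple_course.days
        assert ncourse.scores == simple_course.scores
        assert ncourse.endpoint_day == simple_course.endpoint_day


class TestRollingStats:
    def test_hand_computed_example(self):
        mean, sd = wb.rolling_stats([100.0, 102.0, 98.0, 95.0], 3)
        # window {100, 102, 98}: mean 100, sample SD 2
        assert mean[3] == pytest.approx(100.0)
        assert sd[3] == pytest.approx(2.0)
        assert np.isnan(mean[:3]).all() and np.isnan(sd[:3]).all()

    def test_constant_values_zero_sd(self):
        mean, sd = wb.rolling_stats([100.0] * 6, 3)
        assert np.allclose(mean[3:], 100.0)
        assert np.allclose(sd[3:], 0.0)

    def test_too_short_sequence_raises(self):
        with pytest.raises(wb.NoEvaluableDaysError):
            wb.rolling_stats([100.0, 101.0, 99.0], 3)

    def test_current_day_excluded_from_window(self):
        # a huge final value must not leak into its own window statistics
        mean, sd = wb.rolling_stats([100.0, 100.0, 100.0, 500.0], 3)
        assert mean[3] == pytest.approx(100.0)
        assert sd[3] == pytest.approx(0.0)

    def test_matches_brute_force_on_200_random_sequences(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n = int(rng.integers(8, 41))
            window = int(rng.integers(2, min(7, n - 1)))
            values = 100.0 + rng.normal(0, 3, size=n)
            mean, sd = wb.rolling_stats(values, window)
            oracle = brute_force_rolling(list(values), window)
            for d, (m, s) in oracle.items():
                assert abs(mean[d] - m) < 1e-9
                assert abs(sd[d] - s) < 1e-9


class TestMadNarrowing:
    @pytest.mark.parametrize(
        "window_mean, observed, applied",
        [
            (100.0, 95.0, 5),    # deficit of 5 -> narrow by 5
            (100.0, 101.0, 0),   # above the mean -> clamp at zero
            (100.0, 99.5, 1),    # half-way rounds up
            (100.0, 99.4, 1),    # 0.6 rounds up
            (100.0, 99.6, 0),    # 0.4 rounds down
            (100.0, 100.0, 0),
        ],
    )
    def test_round_half_up_and_clamp(self, window_mean, observed, applied):
        assert mad_narrowing(window_mean, observed) == applied


class TestComputeBoundaries:
    def test_regular_mode_symmetric_bands(self):
        course = wb.WeightCourse(
            "r1", tuple(range(5)), (100.0, 102.0, 98.0, 100.0, 97.0)
        )
        config = wb.DetectorConfig(window_size=3, width_factor=2.5, mode="regular")
        b = wb.compute_boundaries(wb.normalize_course(course), config)
        assert b.days == (3, 4)
        for m, s, lo, up, n in zip(
            b.moving_mean, b.moving_sd, b.lower, b.upper, b.narrowing
        ):
            assert n == 0.0
            assert lo == pytest.approx(m - 2.5 * s)
            assert up == pytest.approx(m + 2.5 * s)

    def test_mad_mode_narrows_toward_mean(self):
        # window {100, 102, 98} -> mean 100, SD 2; observed 95 -> deficit 5;
        # base lower 95 narrows up to the mean (clamped there)
        course = wb.WeightCourse(
            "r1", tuple(range(4)), (100.0, 102.0, 98.0, 95.0)
        )
        config = wb.DetectorConfig(window_size=3, width_factor=2.5, mode="mad")
        b = wb.compute_boundaries(wb.normalize_course(course), config)
        assert b.narrowing == (5.0,)
        assert b.lower[0] == pytest.approx(100.0)

    def test_mad_mode_above_mean_leaves_boundaries(self):
        course = wb.WeightCourse(
            "r1", tuple(range(4)), (100.0, 102.0, 98.0, 101.0)
        )
        config = wb.DetectorConfig(window_size=3, width_factor=2.5, mode="mad")
        b = wb.compute_boundaries(wb.normalize_course(course), config)
        assert b.narrowing == (0.0,)
        assert b.lower[0] == pytest.approx(100.0 - 2.5 * 2.0)

    def test_score_mode_requires_scores(self, simple_course):
        course = wb.WeightCourse(
            simple_course.animal_id, simple_course.days, simple_course.weights
        )
        config = wb.DetectorConfig(mode="score")
        with pytest.raises(wb.ConfigurationError, match="score"):
            wb.compute_boundaries(wb.normalize_course(course), config)

    def test_score_mode_narrowing_proportional_to_score(self, simple_course):
        config = wb.DetectorConfig(mode="score", score_narrowing_unit=1.5)
        b = wb.compute_boundaries(wb.normalize_course(simple_course), config)
        narrowing_by_day = dict(zip(b.days, b.narrowing))
        endpoint = simple_course.endpoint_day
        assert narrowing_by_day[endpoint] == pytest.approx(1.5 * 2)
        assert narrowing_by_day[endpoint - 1] == pytest.approx(1.5 * 1)
        assert narrowing_by_day[endpoint - 2] == 0.0

    def test_boundaries_never_cross_the_mean(self, training_cohort):
        for mode in ("regular", "mad", "score"):
            config = wb.DetectorConfig(window_size=4, width_factor=0.5, mode=mode)
            for course in training_cohort:
                b = wb.compute_boundaries(wb.normalize_course(course), config)
                for m, lo, up in zip(b.moving_mean, b.lower, b.upper):
                    assert lo <= m + 1e-12
                    assert up >= m - 1e-12


class TestDetectAlarms:
    def _single_day(self, pct_final):
        course = wb.WeightCourse(
            "r1", tuple(range(4)), (100.0, 102.0, 98.0, pct_final)
        )
        ncourse = wb.normalize_course(course)
        config = wb.DetectorConfig(window_size=3, width_factor=2.5)
        boundaries = wb.compute_boundaries(ncourse, config)
        return wb.detect_alarms(ncourse, boundaries), boundaries

    def test_strictly_below_lower_alarms(self):
        alarms, b = self._single_day(94.9)
        assert b.lower[0] == pytest.approx(95.0)
        assert alarms == {3}

    def test_exactly_on_lower_does_not_alarm(self):
        alarms, b = self._single_day(95.0)
        assert alarms == frozenset()

    def test_upper_crossing_never_alarms(self):
        alarms, b = self._single_day(107.0)
        assert b.upper[0] == pytest.approx(105.0)
        assert alarms == frozenset()


class TestRunDetector:
    def test_constant_course_single_terminal_drop(self):
        # SD of a constant window is 0, so boundaries collapse to the mean
        # and any strict drop alarms — exactly once, on the endpoint day
        course = make_constant_drop_course(n_days=16, drop_pct=10.0)
        config = wb.DetectorConfig(window_size=6, width_factor=2.5)
        _, alarms = wb.run_detector(course, config)
        assert alarms == {course.endpoint_day}

    def test_course_no_longer_than_window_raises(self):
        course = make_constant_drop_course(n_days=6)
        with pytest.raises(wb.NoEvaluableDaysError):
            wb.run_detector(course, wb.DetectorConfig(window_size=6))

    def test_deterministic(self, training_cohort):
        course = training_cohort.courses[0]
        config = wb.DetectorConfig()
        b1, a1 = wb.run_detector(course, config)
        b2, a2 = wb.run_detector(course, config)
        assert a1 == a2
        assert b1 == b2


class TestDetectorProperties:
    @settings(max_examples=40, derandomize=True)
    @given(
        data=st.lists(
            st.floats(min_value=50.0, max_value=150.0), min_size=8, max_size=25
        ),
        k1=st.floats(min_value=0.5, max_value=1.5),
        dk=st.floats(min_value=0.1, max_value=1.5),
        scale=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_width_monotonicity_and_scale_invariance(self, data, k1, dk, scale):
        course = wb.WeightCourse(
            "h", tuple(range(len(data))), tuple(200.0 + x for x in data)
        )
        narrow = wb.DetectorConfig(window_size=4, width_factor=k1)
        wide = wb.DetectorConfig(window_size=4, width_factor=k1 + dk)
        _, alarms_narrow = wb.run_detector(course, narrow)
        _, alarms_wide = wb.run_detector(course, wide)
        assert alarms_wide <= alarms_narrow

        scaled = wb.WeightCourse(
            "h", course.days, tuple(w * scale for w in course.weights)
        )
        _, alarms_scaled = wb.run_detector(scaled, narrow)
        assert alarms_scaled == alarms_narrow

    def test_mode_nesting_on_synthetic_cohort(self, training_cohort):
        """Constrained lower boundaries sit at or above the regular ones, so
        regular alarms are a subset of mad- and score-mode alarms."""
        base = dict(window_size=6, width_factor=2.5)
        for course in training_cohort:
            results = {}
            for mode in ("regular", "mad", "score"):
                b, alarms = wb.run_detector(
                    course, wb.DetectorConfig(mode=mode, **base)
                )
                results[mode] = (b, alarms)
            b_reg, alarms_reg = results["regular"]
            for mode in ("mad", "score"):
                b_mode, alarms_mode = results[mode]
                assert alarms_reg <= alarms_mode
                for lo_r, lo_m in zip(b_reg.lower, b_mode.lower):
                    assert lo_r <= lo_m + 1e-12
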