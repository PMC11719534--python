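"""Curve feature extraction and A-D perfusion typing."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from parotid_dx.cohort_sim import DceTiming, generate_dce_series
from parotid_dx.dce_analysis import (
    CurveClassifierConfig,
    CurveFeatures,
    SignalTimeCurve,
    aggregate_roi_curves,
    classify_curve,
    extract_features,
    type_curve,
    type_curves_majority,
)


def _features(peak_time, washout, enhancement=1.5):
    return CurveFeatures(
        baseline_si=100.0, peak_si=100.0 * (1 + enhancement),
        peak_time_s=peak_time, end_si=0.0, washout_pct=washout,
        enhancement_fraction=enhancement,
        washout_defined=not math.isnan(washout),
    )


class TestSignalTimeCurve:
    def test_validates_lengths_and_monotonicity(self):
        with pytest.raises(ValueError, match="equal length"):
            SignalTimeCurve(np.arange(5.0), np.zeros(4), 1)
        with pytest.raises(ValueError, match="strictly increasing"):
            SignalTimeCurve(np.array([0.0, 2.0, 1.0, 3.0]), np.zeros(4), 1)
        with pytest.raises(ValueError, match="2 frames past"):
            SignalTimeCurve(np.arange(3.0), np.zeros(3), 2)

    def test_injection_time_is_first_post_baseline_frame(self):
        t = DceTiming()
        assert t.injection_time_s == pytest.approx(4 * 6.6)


class TestExtractFeatures:
    def test_piecewise_linear_washout(self):
        # baseline 100, peak 300, end 160 -> washout (300-160)/(300-100) = 70%
        curve = generate_dce_series("B", 99.0, 70.0, 100.0, 200.0)
        f = extract_features(curve)
        assert f.baseline_si == pytest.approx(100.0)
        assert f.peak_si == pytest.approx(300.0)
        assert f.end_si == pytest.approx(160.0)
        assert f.washout_pct == pytest.approx(70.0)

    def test_constant_curve_flagged_undefined(self):
        curve = SignalTimeCurve(np.arange(10.0), np.full(10, 100.0), 4)
        f = extract_features(curve)
        assert f.enhancement_fraction == 0.0
        assert not f.washout_defined
        assert math.isnan(f.washout_pct)

    def test_round_trip_of_generated_type_b(self):
        curve = generate_dce_series("B", 100.0, 64.0, 100.0, 200.0)
        f = extract_features(curve)
        assert abs(f.peak_time_s - 100.0) <= 6.6 / 2
        assert f.washout_pct == pytest.approx(64.0, abs=0.5)

    def test_peak_first_occurrence_on_ties(self):
        signals = np.array([100.0, 100, 100, 100, 100, 200, 200, 150, 120, 110])
        curve = SignalTimeCurve(np.arange(10.0) * 6.6, signals, 4)
        f = extract_features(curve)
        assert f.peak_time_s == pytest.approx(6.6)  # frame 5, not frame 6

    def test_too_few_post_injection_frames_unrepresentable(self):
        # the curve invariant itself forbids < 2 post-injection frames
        with pytest.raises(ValueError, match="2 frames past"):
            SignalTimeCurve(np.arange(5.0), np.ones(5), 4)


class TestAggregate:
    def test_single_curve_identity(self, timing):
        c = generate_dce_series("B", 100.0, 64.0, 100.0, 200.0, timing)
        agg = aggregate_roi_curves([c])
        np.testing.assert_allclose(agg.signals, c.signals)

    def test_mean_of_constants(self):
        t = np.arange(10.0)
        c1 = SignalTimeCurve(t, np.full(10, 100.0), 4)
        c2 = SignalTimeCurve(t, np.full(10, 200.0), 4)
        agg = aggregate_roi_curves([c1, c2])
        np.testing.assert_allclose(agg.signals, 150.0)

    def test_identical_copies_preserve_features(self):
        c = generate_dce_series("B", 80.0, 55.0, 100.0, 200.0)
        agg = aggregate_roi_curves([c] * 5)
        f1, f5 = extract_features(c), extract_features(agg)
        assert f1 == f5

    def test_mismatched_grids_rejected(self):
        c1 = SignalTimeCurve(np.arange(10.0), np.zeros(10), 4)
        c2 = SignalTimeCurve(np.arange(10.0) * 2, np.zeros(10), 4)
        with pytest.raises(ValueError, match="time grid"):
            aggregate_roi_curves([c1, c2])

    def test_majority_vote_alternative(self):
        b = generate_dce_series("B", 80.0, 55.0, 100.0, 200.0)
        c = generate_dce_series("C", 80.0, 10.0, 100.0, 200.0)
        assert type_curves_majority([b, b, c]) == "B"


class TestClassifyCurve:
    @pytest.mark.parametrize(
        "peak_time,washout,enhancement,expected",
        [
            (150.0, 50.0, 1.5, "A"),
            (100.0, 47.0, 1.5, "B"),   # low end of reported WT washouts
            (100.0, 10.0, 1.5, "C"),
            (100.0, 50.0, 0.0, "D"),   # flat
            (100.0, 50.0, 0.19, "D"),  # just below the flat cut
            (120.0, 50.0, 1.5, "B"),   # peak exactly at the cut is NOT type A
            (120.0, 10.0, 1.5, "C"),
            (100.0, 30.0, 1.5, "B"),   # washout exactly at the cut IS type B
            (100.0, 29.99, 1.5, "C"),
        ],
    )
    def test_taxonomy(self, peak_time, washout, enhancement, expected):
        assert classify_curve(_features(peak_time, washout, enhancement)) == expected

    def test_undefined_washout_with_enhancement_is_unclassifiable(self):
        feats = CurveFeatures(
            baseline_si=100.0, peak_si=250.0, peak_time_s=60.0, end_si=200.0,
            washout_pct=math.nan, enhancement_fraction=1.5,
            washout_defined=False)
        with pytest.raises(ValueError, match="unclassifiable"):
            classify_curve(feats)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CurveClassifierConfig(peak_time_cut_s=0)

    @given(
        peak_time=st.floats(1.0, 400.0),
        washout=st.floats(0.0, 100.0),
        enhancement=st.floats(0.0, 5.0),
    )
    def test_total_partition(self, peak_time, washout, enhancement):
        """Every defined feature vector maps to exactly one of A/B/C/D."""
        label = classify_curve(_features(peak_time, washout, enhancement))
        assert label in {"A", "B", "C", "D"}


class TestGeneratorRoundTrip:
    @pytest.mark.parametrize("curve_type", ["A", "B", "C"])
    @pytest.mark.parametrize("washout", [0.0, 15.0, 29.9, 30.0, 64.0, 100.0])
    @pytest.mark.parametrize("peak_time", [20.0, 66.0, 118.0, 121.0, 150.0, 250.0])
    def test_noise_free_curves_recover_their_type(self, curve_type, washout,
                                                  peak_time):
        if curve_type == "B" and washout < 30:
            washout = 30.0
        if curve_type == "C" and washout >= 30:
            washout = 29.9
        curve = generate_dce_series(curve_type, peak_time, washout, 100.0, 200.0)
        assert type_curve(curve)[0] == curve_type

    def test_type_d_is_constant_baseline(self, timing):
        curve = generate_dce_series("D", math.nan, math.nan, 100.0, 0.0, timing)
        np.testing.assert_array_equal(curve.signals, 100.0)
        assert len(curve) == 51
        assert type_curve(curve)[0] == "D"

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="washout"):
            generate_dce_series("B", 100.0, 120.0, 100.0, 200.0)
        with pytest.raises(ValueError, match="peak_time"):
            generate_dce_series("B", -5.0, 50.0, 100.0, 200.0)
        with pytest.raises(ValueError, match="amplitude"):
            generate_dce_series("B", 100.0, 50.0, 100.0, 0.0)
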