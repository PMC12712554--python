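"""Analysis layer: reverse correlation, normalization, change points."""

import numpy as np
import pytest

from saccatt import ParameterSet
from saccatt.analysis import (
    ALPHA,
    ConditionCurve,
    build_condition_curves,
    detect_change,
    normalize_curves,
    reverse_correlate,
    visual_noise_floor,
)
from saccatt.experiment import FP, ST, TrialConfig, TrialRecord
from saccatt.fixtures import make_fixture_records
from saccatt.signals import BarStimulus, make_eye_trajectory


def _record_with(bars, fill, params, shape_fn=None):
    """Hand-built record: V4 rows filled with a prescribed rate pattern."""
    traj = make_eye_trajectory(FP, ST, params.saccade_onset, params=params)
    n_steps = int(params.trial_duration)
    rows = np.full((n_steps, 2, 41), fill, dtype=np.float32)
    if shape_fn is not None:
        shape_fn(rows)
    return TrialRecord(
        config=TrialConfig(ap_index=0, seed=0),
        bars=bars,
        trajectory=traj,
        v4_rows=rows,
        row_y=(params.ap_offset_deg, -params.ap_offset_deg),
    )


class TestReverseCorrelation:
    def test_constant_rate_neuron_yields_that_constant(self, params):
        bars = [BarStimulus(0.0, 5.0, onset=100.0, duration=10.0, side="above")]
        rec = _record_with(bars, 0.37, params)
        (resp,) = reverse_correlate([rec], params)
        assert resp.response == pytest.approx(0.37)
        assert resp.condition == "AU"
        assert resp.locus == (0.0, 5.0)

    def test_no_bars_yields_empty_output(self, params):
        rec = _record_with([], 0.5, params)
        assert reverse_correlate([rec], params) == []

    def test_known_ramp_gives_hand_computed_window_mean(self, params):
        """Oracle: rate ramps 0..0.95 over the 20 ms window in steps of 0.05."""
        bars = [BarStimulus(-3.0, -5.0, onset=200.0, duration=15.0, side="below")]

        def ramp(rows):
            col = 17  # x = -3 deg
            rows[200:220, 1, col] = np.arange(20) * 0.05

        rec = _record_with(bars, 0.0, params, ramp)
        (resp,) = reverse_correlate([rec], params)
        assert resp.response == pytest.approx(np.mean(np.arange(20) * 0.05))

    def test_bar_outside_field_is_skipped(self, params):
        bars = [BarStimulus(-19.0, 5.0, onset=660.0, duration=10.0, side="above")]
        # onset after saccade: retinotopic locus = -24 deg, outside the field
        rec = _record_with(bars, 0.4, params)
        assert reverse_correlate([rec], params) == []

    def test_postsaccadic_bar_over_ap_maps_to_au_neuron(self, params):
        bars = [BarStimulus(5.0, 5.0, onset=600.0, duration=10.0, side="above")]
        rec = _record_with(bars, 0.2, params)
        (resp,) = reverse_correlate([rec], params)
        assert resp.locus == (0.0, 5.0)
        assert resp.condition == "AU"


def _curve(bin_starts, samples_per_bin):
    return ConditionCurve("X", np.asarray(bin_starts, float), [np.asarray(s, float) for s in samples_per_bin])


class TestCurvesAndNormalization:
    def test_identical_samples_give_their_value_and_zero_dispersion(self):
        c = _curve([0, 20], [[0.3, 0.3, 0.3], [0.3, 0.3]])
        assert c.mean == pytest.approx([0.3, 0.3])
        assert c.sd == pytest.approx([0.0, 0.0])

    def test_two_samples_average_to_their_midpoint(self):
        c = _curve([0], [[0.2, 0.6]])
        assert c.mean == pytest.approx([0.4])

    def test_au_equal_to_uu_normalizes_to_zero(self):
        au = _curve([0, 20], [[0.3, 0.3], [0.5, 0.5]])
        uu = _curve([0, 20], [[0.3, 0.3], [0.5, 0.5]])
        ua = _curve([0, 20], [[0.1], [0.1]])
        au_n, _ = normalize_curves(au, ua, uu)
        assert au_n.mean == pytest.approx([0.0, 0.0])

    def test_constant_offset_is_recovered_binwise(self):
        rng = np.random.default_rng(0)
        uu_samples = [rng.uniform(0.2, 0.4, 30) for _ in range(5)]
        au_samples = [s + 0.15 for s in uu_samples]
        au = _curve(range(0, 100, 20), au_samples)
        uu = _curve(range(0, 100, 20), uu_samples)
        au_n, _ = normalize_curves(au, au, uu)
        assert au_n.mean == pytest.approx(np.full(5, 0.15), abs=1e-12)

    def test_bin_mismatch_raises(self):
        au = _curve([0, 20], [[1.0], [1.0]])
        uu = _curve([0, 40], [[1.0], [1.0]])
        with pytest.raises(ValueError, match="bins"):
            normalize_curves(au, au, uu)

    def test_condition_pooling_from_responses(self, params):
        from saccatt.analysis import ProbeResponse

        responses = [
            ProbeResponse(0, "AU", -295.0, (0, 5), 0.5),
            ProbeResponse(1, "AU", -290.0, (0, 5), 0.7),
            ProbeResponse(0, "UU", -290.0, (0, -5), 0.2),
            ProbeResponse(0, "none", -290.0, (9, 5), 9.9),
        ]
        curves = build_condition_curves(responses, params)
        assert curves["AU"].samples[0].tolist() == [0.5, 0.7]
        assert curves["UU"].samples[0].tolist() == [0.2]
        assert curves["UA"].n.sum() == 0


class TestChangePointDetection:
    def _noisy_curve(self, active, n=40, effect=0.5, seed=0):
        """Normalized curve with given per-bin activity flags."""
        rng = np.random.default_rng(seed)
        starts = np.arange(-300, 300, 20.0)
        samples = [rng.normal(effect * a, 0.15, size=n) for a in active]
        return ConditionCurve("AU-UU", starts, samples)

    def test_significant_everywhere_gives_no_offset_and_immediate_onset(self):
        c = self._noisy_curve([1] * 30)
        assert detect_change(c, "offset-in-AU").time_ms is None
        assert detect_change(c, "onset-in-UA").time_ms == -300.0

    def test_constructed_change_point_is_recovered_within_one_bin(self):
        for b in (5, 12, 25):
            active = [1] * b + [0] * (30 - b)
            c = self._noisy_curve(active, seed=b)
            off = detect_change(c, "offset-in-AU").time_ms
            assert abs(off - (-300 + 20 * b)) <= 20.0
            on = detect_change(self._noisy_curve(active[::-1], seed=b), "onset-in-UA").time_ms
            assert abs(on - (-300 + 20 * (30 - b))) <= 20.0

    def test_all_zero_series_has_no_onset(self):
        c = self._noisy_curve([0] * 30)
        assert detect_change(c, "onset-in-UA").time_ms is None

    def test_detection_is_idempotent(self):
        c = self._noisy_curve([1] * 10 + [0] * 20, seed=5)
        r1 = detect_change(c, "offset-in-AU")
        r2 = detect_change(c, "offset-in-AU")
        assert r1.time_ms == r2.time_ms
        assert np.array_equal(r1.p_values, r2.p_values)

    def test_short_final_run_does_not_qualify(self):
        # only the last two windows lose significance: no offset
        c = self._noisy_curve([1] * 28 + [0] * 2)
        assert detect_change(c, "offset-in-AU").time_ms is None

    def test_null_false_positive_rate_matches_three_window_rule(self):
        """On pure-noise curves the onset detector fires at most at the
        nominal rate of the triple-window rule (~28 * alpha^3 per curve)."""
        fired = 0
        reps = 400
        for k in range(reps):
            c = self._noisy_curve([0] * 30, seed=1000 + k)
            if detect_change(c, "onset-in-UA").time_ms is not None:
                fired += 1
        assert fired / reps <= 0.02

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            detect_change(self._noisy_curve([0] * 30), "sideways")


class TestVisualNoiseFloor:
    def test_threshold_arithmetic_and_monotonicity(self):
        uu = _curve([0, 20], [[0.5, 0.7], [0.6, 0.6]])  # max mean = 0.6
        out = visual_noise_floor(np.array([0.1, 0.3, 0.6, 0.9]), uu)
        assert out == pytest.approx([0.0, 0.0, 0.3, 0.6])
        assert np.all(np.diff(out) >= 0)


class TestPlantedFixtures:
    @pytest.mark.parametrize(
        "kind,au_off,ua_on",
        [
            ("remap+linger", 200.0, -100.0),
            ("remap-only", -20.0, -100.0),
        ],
    )
    def test_planted_change_points_recovered_within_one_bin(self, kind, au_off, ua_on, params):
        from saccatt.analysis import analyze_records

        records = make_fixture_records(kind, seed=2, n_trials=150, params=params)
        s = analyze_records(records, params)
        assert s.offset_au.time_ms is not None
        assert abs(s.offset_au.time_ms - au_off) <= 20.0
        assert s.onset_ua.time_ms is not None
        assert abs(s.onset_ua.time_ms - ua_on) <= 20.0

    def test_null_fixture_detects_nothing(self, params):
        from saccatt.analysis import analyze_records

        records = make_fixture_records("null", seed=3, n_trials=80, params=params)
        s = analyze_records(records, params)
        assert s.onset_ua.time_ms is None
        assert s.offset_au.time_ms == -300.0  # never significant from the start

    def test_planted_structure_appears_in_condition_curves(self, params):
        from saccatt.analysis import analyze_records

        records = make_fixture_records("remap+linger", seed=4, n_trials=60, params=params)
        s = analyze_records(records, params)
        early = slice(0, 5)
        late = slice(25, 30)
        assert np.nanmean(s.au_norm.mean[early]) > 0.05
        assert np.nanmean(s.ua_norm.mean[early]) < 0.03
        assert np.nanmean(s.ua_norm.mean[late]) > 0.05

    def test_unknown_kind_rejected(self, params):
        with pytest.raises(ValueError, match="kind"):
            make_fixture_records("bogus", seed=0, params=params)
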