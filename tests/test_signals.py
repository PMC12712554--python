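"""Input-signal generators: kinematics, bar streams, PC/CD/attention."""

import numpy as np
import pytest

from saccatt import FieldGeometry, ParameterSet
from saccatt.signals import (
    AttentionSchedule,
    attention_amplitude,
    attention_signal,
    cd_seed_signal,
    generate_bar_stream,
    make_eye_trajectory,
    pc_amplitudes,
    pc_signal,
    render_visual_input,
    saccade_duration,
)


class TestSaccadeKinematics:
    def test_five_degree_saccade_lasts_67_ms(self):
        assert saccade_duration(5.0) == pytest.approx(67.0)

    def test_zero_amplitude_saccade_has_zero_duration(self):
        assert saccade_duration(0.0) == 0.0

    def test_ten_degree_duration_matches_main_sequence_by_hand(self):
        # affine main sequence: 42 ms + 5 ms/deg * 10 deg
        assert saccade_duration(10.0) == pytest.approx(42.0 + 5.0 * 10.0)

    def test_eye_lands_on_target_after_saccade(self, trajectory):
        assert trajectory.saccade_duration == pytest.approx(67.0)
        for t in (417.0, 450.0, 699.0):
            x, y = trajectory.position(t)
            assert (x, y) == pytest.approx((5.0, 0.0))
        assert trajectory.position(349.0) == pytest.approx((0.0, 0.0))

    def test_position_is_monotone_and_continuous_along_saccade(self, trajectory):
        t = np.arange(340.0, 430.0, 0.5)
        xs = trajectory.position(t)[:, 0]
        assert np.all(np.diff(xs) >= 0)
        assert np.max(np.abs(np.diff(xs))) < 0.3  # no jumps at 0.5 ms resolution

    def test_identical_endpoints_give_constant_position(self, geometry):
        traj = make_eye_trajectory((2.0, 1.0), (2.0, 1.0), 350.0, geometry)
        for t in (0.0, 350.0, 400.0, 699.0):
            assert traj.position(t) == pytest.approx((2.0, 1.0))

    def test_positions_outside_field_raise_naming_the_bound(self, geometry):
        with pytest.raises(ValueError, match="half-width"):
            make_eye_trajectory((0.0, 0.0), (25.0, 0.0), 350.0, geometry)
        with pytest.raises(ValueError, match="half-height"):
            make_eye_trajectory((0.0, 16.0), (5.0, 0.0), 350.0, geometry)


class TestBarStream:
    def test_bars_respect_window_duration_and_sides(self, geometry, trajectory, params):
        bars = generate_bar_stream(geometry, trajectory, seed=5, params=params)
        onsets = np.array([b.onset for b in bars])
        durations = np.array([b.duration for b in bars])
        assert np.all(onsets >= params.saccade_onset - 300.0)
        assert np.all(onsets <= params.saccade_onset + 300.0)
        assert np.all((durations >= 5.0) & (durations <= 20.0))
        sides = {b.side for b in bars}
        assert sides == {"above", "below"}
        assert all(abs(b.y_deg) == params.ap_offset_deg for b in bars)

    def test_same_seed_reproduces_stream_element_for_element(self, geometry, trajectory):
        a = generate_bar_stream(geometry, trajectory, seed=11)
        b = generate_bar_stream(geometry, trajectory, seed=11)
        assert a == b
        c = generate_bar_stream(geometry, trajectory, seed=12)
        assert a != c

    def test_zero_length_window_yields_empty_stream(self, geometry, trajectory, params):
        p = params.replace(bar_window=0.0)
        assert generate_bar_stream(geometry, trajectory, seed=3, params=p) == []

    def test_concurrent_same_side_bars_keep_min_distance(self, geometry, trajectory, params):
        bars = generate_bar_stream(geometry, trajectory, seed=7, params=params)
        for i, a in enumerate(bars):
            for b in bars[i + 1 :]:
                if a.side == b.side and a.onset < b.offset and b.onset < a.offset:
                    assert abs(a.x_deg - b.x_deg) >= params.bar_min_distance

    def test_per_side_onsets_are_spaced(self, geometry, trajectory, params):
        bars = generate_bar_stream(geometry, trajectory, seed=9, params=params)
        for side in ("above", "below"):
            onsets = sorted(b.onset for b in bars if b.side == side)
            assert np.min(np.diff(onsets)) >= params.bar_min_onset_gap - 1e-9


class TestVisualRendering:
    def _peak(self, img, geometry):
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        return geometry.to_deg(iy, ix)

    def test_blob_at_head_position_when_eyes_at_origin(self, geometry, trajectory, params):
        from saccatt.signals import BarStimulus

        bar = BarStimulus(5.0, 3.0, onset=100.0, duration=15.0, side="above")
        img = render_visual_input([bar], trajectory, 105.0, geometry, params)
        assert self._peak(img, geometry) == pytest.approx((5.0, 3.0))

    def test_blob_shifts_by_negative_eye_displacement(self, geometry, params):
        from saccatt.signals import BarStimulus

        traj = make_eye_trajectory((0.0, 0.0), (5.0, 0.0), 10.0, geometry, params)
        bar = BarStimulus(5.0, 3.0, onset=200.0, duration=15.0, side="above")
        img = render_visual_input([bar], traj, 205.0, geometry, params)
        assert self._peak(img, geometry) == pytest.approx((0.0, 3.0))

    def test_blob_traces_negative_eye_trajectory_during_saccade(self, geometry, trajectory, params):
        """Brute-force oracle: the blob center equals head - eye at each step."""
        from saccatt.signals import BarStimulus

        bar = BarStimulus(2.0, 5.0, onset=340.0, duration=80.0, side="above")
        for t in np.arange(345.0, 420.0, 7.0):
            img = render_visual_input([bar], trajectory, t, geometry, params)
            ex, ey = trajectory.position(t)
            expect = (round(2.0 - ex), round(5.0 - ey))
            assert self._peak(img, geometry) == pytest.approx(expect)


class TestPCSignal:
    def test_pc_holds_presaccadic_position_through_saccade(self, geometry, trajectory, params):
        img = pc_signal(trajectory, trajectory.saccade_onset, geometry, params)
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert geometry.to_deg(iy, ix) == pytest.approx(trajectory.fp)

    def test_pc_encodes_target_long_after_update(self, geometry, trajectory, params):
        t = trajectory.saccade_end + params.pc_update_delay + params.pc_swap_duration + 50
        img = pc_signal(trajectory, t, geometry, params)
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert geometry.to_deg(iy, ix) == pytest.approx(trajectory.st)

    def test_no_saccade_keeps_pc_at_fixation(self, geometry, params):
        traj = make_eye_trajectory((1.0, 2.0), (1.0, 2.0), 350.0, geometry, params)
        for t in (0.0, 400.0, 699.0):
            img = pc_signal(traj, t, geometry, params)
            iy, ix = np.unravel_index(np.argmax(img), img.shape)
            assert geometry.to_deg(iy, ix) == pytest.approx((1.0, 2.0))

    def test_two_state_property_amplitudes_never_both_above_half(self, trajectory, params):
        t = np.arange(0.0, 700.0, 1.0)
        a_old, a_new = pc_amplitudes(trajectory, t, params)
        assert np.all(a_old + a_new == pytest.approx(1.0))
        assert not np.any((a_old > 0.5 + 1e-9) & (a_new > 0.5 + 1e-9))


class TestCDSeed:
    def test_baseline_is_below_one_percent_of_peak(self, params):
        t = np.arange(0.0, 700.0)
        amp = cd_seed_signal((5.0, 0.0), 350.0, t, params)
        assert amp[0] < 0.01 * amp.max()
        assert amp[-1] < 0.01 * amp.max()

    def test_profile_is_unimodal(self, params):
        t = np.arange(0.0, 700.0)
        amp = cd_seed_signal((5.0, 0.0), 350.0, t, params)
        d = np.sign(np.diff(amp))
        # one sign change from rising to falling (ignoring flat stretches)
        changes = np.diff(d[d != 0])
        assert np.sum(changes < 0) == 1

    def test_peak_at_or_before_saccade_onset(self, params):
        t = np.arange(0.0, 700.0)
        amp = cd_seed_signal((5.0, 0.0), 350.0, t, params)
        assert t[np.argmax(amp)] <= 350.0


class TestAttention:
    def test_tonic_amplitude_plateaus_and_never_decreases(self, params):
        sch = AttentionSchedule(ap=(0.0, 5.0), mode="tonic")
        t = np.arange(0.0, 700.0)
        amp = attention_amplitude(sch, t, 350.0, params)
        assert np.all(np.diff(amp) >= -1e-12)
        assert amp[-1] == pytest.approx(amp[500], rel=0.05)

    def test_fading_keeps_full_amplitude_before_turnoff(self, params):
        sch = AttentionSchedule(ap=(0.0, 5.0), mode="fading", turnoff_time=-100.0)
        tonic = AttentionSchedule(ap=(0.0, 5.0), mode="tonic")
        t = 350.0 - 200.0
        assert attention_amplitude(sch, t, 350.0, params) == pytest.approx(
            attention_amplitude(tonic, t, 350.0, params)
        )

    def test_fading_amplitude_vanishes_well_after_turnoff(self, params):
        sch = AttentionSchedule(ap=(0.0, 5.0), mode="fading", turnoff_time=-100.0)
        peak = attention_amplitude(sch, 350.0 - 101.0, 350.0, params)
        late = attention_amplitude(sch, 350.0 + 100.0, 350.0, params)
        assert late < 0.01 * peak

    def test_attention_map_peaks_at_pointer_position(self, geometry, params):
        sch = AttentionSchedule(ap=(0.0, 5.0), mode="tonic")
        img = attention_signal(sch, 600.0, 350.0, geometry, params)
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert geometry.to_deg(iy, ix) == (0.0, 5.0)

    def test_fading_without_turnoff_is_rejected(self):
        with pytest.raises(ValueError, match="turnoff"):
            AttentionSchedule(ap=(0.0, 5.0), mode="fading")
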