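"""Rotation algebra, angular speed and finite-helical-axis estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from cervkin.kinematics import (
    RotationSequence,
    angular_speed,
    compute_signals,
    euler_to_matrix,
    finite_helical_axis,
    helical_angle,
    lowpass_filter,
    matrix_to_euler_zyx,
    relative_rotation,
    rotation_axis,
)
from cervkin.synthetic import TrialGenParams, generate_trial, minjerk_position
from cervkin.trial_io import ValidationError

from conftest import random_rotation

angles = st.floats(-75.0, 75.0, allow_nan=False)


class TestEulerToMatrix:
    def test_identity(self):
        assert np.allclose(euler_to_matrix([0, 0, 0]), np.eye(3))

    def test_azimuth_quarter_turn_maps_x_to_y(self):
        R = euler_to_matrix([90, 0, 0])
        assert np.allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_matches_quaternion_composition(self):
        """ZYX cardan factorisation agrees with an independent
        quaternion-based implementation to 1e-12."""
        rng = np.random.default_rng(0)
        e = rng.uniform(-180, 180, (500, 3))
        ours = euler_to_matrix(e)
        # scipy Rotation composes through quaternions internally
        theirs = Rotation.from_euler("ZYX", e, degrees=True).as_matrix()
        assert np.max(np.abs(ours - theirs)) < 1e-12

    @given(az=angles, el=angles, ro=angles)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_and_orthonormality(self, az, el, ro):
        R = euler_to_matrix([az, el, ro])
        assert np.linalg.norm(R.T @ R - np.eye(3)) < 1e-12
        assert np.linalg.det(R) > 0
        back = matrix_to_euler_zyx(R)
        assert np.allclose(back, [az, el, ro], atol=1e-9)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            euler_to_matrix([np.nan, 0, 0])


class TestRelativeRotation:
    def test_equal_orientations_give_identity(self):
        rng = np.random.default_rng(1)
        R = random_rotation(rng)
        assert np.allclose(relative_rotation(R, R), np.eye(3), atol=1e-12)

    def test_identity_thorax_returns_head(self):
        rng = np.random.default_rng(2)
        R = random_rotation(rng)
        assert np.allclose(relative_rotation(R, np.eye(3)), R)

    def test_algebraic_inverse(self):
        rng = np.random.default_rng(3)
        head, thorax = random_rotation(rng), random_rotation(rng)
        M = relative_rotation(head, thorax)
        assert np.allclose(thorax @ M, head, atol=1e-12)

    def test_rejects_non_rotation(self):
        with pytest.raises(ValidationError):
            relative_rotation(np.eye(3) * 2, np.eye(3))


class TestHelicalAngle:
    def test_identity_is_zero(self):
        assert helical_angle(np.eye(3)) == 0.0

    @pytest.mark.parametrize("axis", ["x", "y", "z"])
    def test_quarter_turn(self, axis):
        R = Rotation.from_euler(axis, 90, degrees=True).as_matrix()
        assert helical_angle(R) == pytest.approx(90.0, abs=1e-9)

    def test_composition_matches_quaternion_oracle(self):
        Rz = Rotation.from_euler("z", 30, degrees=True)
        Rx = Rotation.from_euler("x", 40, degrees=True)
        composed = Rx * Rz
        expected = np.degrees(composed.magnitude())
        assert helical_angle(composed.as_matrix()) == pytest.approx(expected, abs=1e-10)

    def test_angle_symmetry_under_transpose(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            R = random_rotation(rng)
            assert helical_angle(R) == pytest.approx(helical_angle(R.T), abs=1e-9)

    def test_with_reference(self):
        rng = np.random.default_rng(5)
        ref = random_rotation(rng)
        R = Rotation.from_matrix(ref) * Rotation.from_euler("z", 25, degrees=True)
        assert helical_angle(R.as_matrix(), ref) == pytest.approx(25.0, abs=1e-9)


def _single_axis_sequence(axis, rate_deg_s, fs=60.0, duration=1.0):
    t = np.arange(0, duration, 1 / fs)
    rots = Rotation.from_rotvec(np.radians(rate_deg_s * t)[:, None] * np.asarray(axis))
    return RotationSequence(time_s=t, M=rots.as_matrix())


class TestAngularSpeed:
    def test_static_sequence_is_zero(self):
        t = np.arange(0, 1, 1 / 60)
        seq = RotationSequence(time_s=t, M=np.tile(np.eye(3), (t.size, 1, 1)))
        assert np.allclose(angular_speed(seq), 0.0, atol=1e-12)

    def test_constant_rate_single_axis(self):
        seq = _single_axis_sequence([0, 0, 1], 100.0)
        speed = angular_speed(seq)
        assert np.allclose(speed[1:-1], 100.0, atol=0.1)

    def test_time_reversal_preserves_magnitude(self):
        seq = _single_axis_sequence([0.6, 0, 0.8], 120.0)
        rev = RotationSequence(time_s=seq.time_s, M=seq.M[::-1].copy())
        assert np.allclose(angular_speed(seq), angular_speed(rev)[::-1], atol=1e-6)

    def test_frame_invariance(self):
        """A constant world-frame rotation of the whole sequence leaves the
        speed magnitudes unchanged."""
        rng = np.random.default_rng(6)
        seq = _single_axis_sequence([0, 1, 0], 150.0)
        Q = random_rotation(rng)
        rotated = RotationSequence(time_s=seq.time_s, M=Q[None] @ seq.M)
        assert np.allclose(angular_speed(seq), angular_speed(rotated), atol=1e-8)

    def test_integral_matches_net_angle(self):
        seq = _single_axis_sequence([0, 0, 1], 90.0, duration=0.8)
        speed = angular_speed(seq)
        integrated = np.trapezoid(speed, seq.time_s)
        net = helical_angle(seq.M[0].T @ seq.M[-1])
        assert abs(integrated - net) < 1.0


def _fha_oracle(M, window_deg):
    """Exhaustive O(N²) search for the reference frame of each FHA window."""
    n = M.shape[0]
    out = np.full((n, 3), np.nan)
    for i in range(n):
        best = None
        for j in range(i):
            R = M[j].T @ M[i]
            if helical_angle(R) >= window_deg:
                best = j  # keep the largest qualifying j
        if best is not None:
            out[i] = rotation_axis(M[best].T @ M[i])
    return out


class TestFiniteHelicalAxis:
    def test_fixed_axis_motion(self):
        seq = _single_axis_sequence([0, 0, 1], 120.0, duration=0.5)
        dirs = finite_helical_axis(seq, 4.0)
        defined = ~np.isnan(dirs[:, 0])
        assert defined.any()
        assert np.allclose(np.abs(dirs[defined] @ [0, 0, 1]), 1.0, atol=1e-6)

    def test_small_rotation_all_undefined(self):
        seq = _single_axis_sequence([0, 0, 1], 3.0, duration=1.0)  # total 3°
        dirs = finite_helical_axis(seq, 4.0)
        assert np.isnan(dirs).all()

    def test_matches_exhaustive_search_oracle(self):
        """Two-phase motion (z-axis then x-axis): windowed nearest-earlier
        search agrees with brute force, and directions migrate between axes."""
        t = np.arange(49) / 60.0
        ang = np.linspace(0, 30, 25)
        phase1 = Rotation.from_euler("z", ang[:, None], degrees=True)
        phase2 = Rotation.from_euler("x", ang[1:, None], degrees=True) * phase1[-1]
        M = np.concatenate([phase1.as_matrix(), phase2.as_matrix()])
        seq = RotationSequence(time_s=t, M=M)
        dirs = finite_helical_axis(seq, 4.0)
        oracle = _fha_oracle(M, 4.0)
        both = ~np.isnan(dirs[:, 0]) & ~np.isnan(oracle[:, 0])
        assert np.array_equal(np.isnan(dirs), np.isnan(oracle))
        assert np.allclose(dirs[both], oracle[both], atol=1e-9)
        assert abs(dirs[20] @ [0, 0, 1]) > 0.99  # early: pure z
        # late: x-axis expressed in the body frame carried by the 30° z-turn
        x_in_body = Rotation.from_euler("z", -30, degrees=True).apply([1, 0, 0])
        assert abs(dirs[-1] @ x_in_body) > 0.99

    def test_world_frame_invariance_up_to_sign(self):
        rng = np.random.default_rng(7)
        seq = _single_axis_sequence([0.6, 0.8, 0], 100.0, duration=0.5)
        dirs = finite_helical_axis(seq, 4.0)
        Q = random_rotation(rng)
        # relabel the moving frame: M -> M Q (time-constant change of basis)
        relabeled = RotationSequence(time_s=seq.time_s, M=seq.M @ Q[None])
        dirs2 = finite_helical_axis(relabeled, 4.0)
        defined = ~np.isnan(dirs[:, 0])
        cos = np.abs(np.sum((dirs[defined] @ Q) * dirs2[defined], axis=1))
        assert np.allclose(cos, 1.0, atol=1e-9)

    def test_rejects_bad_window(self):
        seq = _single_axis_sequence([0, 0, 1], 100.0)
        with pytest.raises(ValueError):
            finite_helical_axis(seq, 0.0)


class TestLowpassFilter:
    def _sine_recording(self, freq, fs=60.0, amp=5.0, duration=2.0):
        from cervkin.trial_io import RawTrialRecording

        t = np.arange(0, duration, 1 / fs)
        chan = amp * np.sin(2 * np.pi * freq * t)
        e = np.column_stack([chan, np.zeros_like(t), np.zeros_like(t)])
        z = np.zeros((t.size, 3))
        return RawTrialRecording(
            subject_id="s", trial_index=1, direction="left", sample_rate_hz=fs,
            time_s=t, head_euler_deg=e, head_pos=z, thorax_euler_deg=z, thorax_pos=z,
        )

    def test_dc_preserved(self):
        rec = self._sine_recording(0.0)
        rec.head_euler_deg[:, 0] = 7.0
        out = lowpass_filter(rec)
        assert np.allclose(out.head_euler_deg[:, 0], 7.0, atol=1e-9)

    def test_passband_gain_matches_analytic_response(self):
        """5 Hz tone through the zero-phase 2nd-order 20 Hz Butterworth:
        measured attenuation equals |H(f)|² of the analytic response."""
        from scipy.signal import butter, freqz

        rec = self._sine_recording(5.0, duration=4.0)
        out = lowpass_filter(rec)
        mid = slice(60, -60)  # avoid filtfilt edge transients
        gain = (
            np.ptp(out.head_euler_deg[mid, 0]) / np.ptp(rec.head_euler_deg[mid, 0])
        )
        b, a = butter(2, 20.0, fs=60.0)
        _, h = freqz(b, a, worN=[5.0], fs=60.0)
        assert gain == pytest.approx(np.abs(h[0]) ** 2, abs=1e-3)

    def test_stopband_attenuates(self):
        rec = self._sine_recording(25.0)
        out = lowpass_filter(rec)
        assert np.ptp(out.head_euler_deg[:, 0]) < np.ptp(rec.head_euler_deg[:, 0])

    def test_rejects_cutoff_at_nyquist(self):
        rec = self._sine_recording(5.0)
        with pytest.raises(ValueError):
            lowpass_filter(rec, cutoff_hz=30.0)


class TestComputeSignals:
    def test_resampled_length_contract(self, clean_signals, clean_trial):
        duration = clean_trial.time_s[-1] - clean_trial.time_s[0]
        assert clean_signals.time_s.size == int(round(duration * 100)) + 1

    def test_helical_angle_tracks_generator_truth(self, clean_trial, clean_signals):
        """Resampled helical angle matches the generator's analytic
        minimum-jerk trajectory within half a degree."""
        T = 1.875 * 60.0 / 300.0
        tau = np.clip((clean_signals.time_s - 0.5) / T, 0, 1)
        expected = 60.0 * minjerk_position(tau)
        err = np.max(np.abs(clean_signals.helical_angle_deg - expected))
        assert err < 0.5

    def test_static_recording_has_negligible_speed(self):
        p = TrialGenParams(peak_speed_deg_s=300, rom_deg=60, seed=1)
        rec = generate_trial(p)
        # freeze all motion channels at the first sample
        for name in ("head_euler_deg", "thorax_euler_deg"):
            arr = getattr(rec, name)
            arr[:] = arr[0]
        sig = compute_signals(rec)
        assert np.max(sig.angular_speed_deg_s) < 1e-6

    def test_signals_are_non_negative(self, realistic_signals):
        assert np.all(realistic_signals.helical_angle_deg >= 0)
        assert np.all(realistic_signals.angular_speed_deg_s >= 0)

    def test_defined_fha_rows_are_unit(self, realistic_signals):
        dirs = realistic_signals.fha_dir
        defined = ~np.isnan(dirs[:, 0])
        norms = np.linalg.norm(dirs[defined], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
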