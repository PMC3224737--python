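"""Segmentation, extrapolation and the six per-trial kinematic variables."""

import numpy as np
import pytest
from scipy.optimize import bisect

from cervkin.kinematics import KinematicSignals
from cervkin.metrics import (
    SegmentationError,
    TrialMetrics,
    aggregate_subject,
    compute_cm,
    compute_metrics,
    compute_sid,
    detect_segment,
    extrapolate_speed,
    flag_atypical,
    process_trial,
)
from cervkin.synthetic import TrialGenParams, generate_trial, minjerk_speed
from cervkin.kinematics import compute_signals

from conftest import random_rotation


def _threshold_roots():
    """Phases where the minimum-jerk speed crosses 10% of its peak, by
    bisection on 30τ²(1−τ)² = 0.1875."""
    f = lambda tau: minjerk_speed(tau) - 0.1 * 1.875
    lo = bisect(f, 1e-6, 0.5, xtol=1e-12)
    hi = bisect(f, 0.5, 1 - 1e-6, xtol=1e-12)
    return lo, hi


def _signals_from_profile(t, theta, speed):
    return KinematicSignals(
        time_s=t,
        helical_angle_deg=theta,
        angular_speed_deg_s=speed,
        fha_time_s=t[:: int(len(t) // 60) or 1],
        fha_dir=np.full((len(t[:: int(len(t) // 60) or 1]), 3), np.nan),
        source_sample_rate_hz=60.0,
    )


class TestDetectSegment:
    def test_threshold_crossings_match_bisection_oracle(self, clean_signals):
        seg = detect_segment(clean_signals)
        lo, hi = _threshold_roots()
        T, t0 = 0.375, 0.5  # generator truth for the clean fixture
        t = clean_signals.time_s
        grid_tau = 0.01 / T
        assert abs((t[seg.start_idx] - t0) / T - lo) <= grid_tau + 1e-9
        assert abs((t[seg.stop_idx] - t0) / T - hi) <= grid_tau + 1e-9

    def test_symmetric_profile_equidistant(self, clean_signals):
        seg = detect_segment(clean_signals)
        t = clean_signals.time_s
        before = t[seg.peak_idx] - t[seg.start_idx]
        after = t[seg.stop_idx] - t[seg.peak_idx]
        assert abs(before - after) <= 0.0101

    def test_monotone_ramp_rejected(self):
        t = np.arange(0, 1, 0.01)
        sig = _signals_from_profile(t, t * 50, t * 100)
        with pytest.raises(SegmentationError, match="truncated"):
            detect_segment(sig)

    def test_unterminated_movement_rejected(self):
        t = np.arange(0, 1, 0.01)
        v = np.where(t < 0.5, 200 * t, 100.0)
        v[0] = 0
        sig = _signals_from_profile(t, np.cumsum(v) * 0.01, v)
        with pytest.raises(SegmentationError, match="unterminated"):
            detect_segment(sig)


class TestExtrapolateSpeed:
    def test_endpoints_are_exactly_zero(self, clean_signals):
        seg = extrapolate_speed(detect_segment(clean_signals), clean_signals)
        assert seg.extrapolated_speed_deg_s[0] == 0.0
        assert seg.extrapolated_speed_deg_s[-1] == 0.0
        assert np.all(seg.extrapolated_speed_deg_s >= 0.0)

    def test_profile_already_at_zero_unchanged(self):
        t = np.arange(0, 1.005, 0.01)
        tau = np.clip(t, 0, 1)
        v = 100 * minjerk_speed(tau)
        v[0] = v[-1] = 0.0
        sig = _signals_from_profile(t, np.cumsum(v) * 0.01, v)
        seg = detect_segment(sig)
        # force full-profile segment: boundaries already at zero speed
        seg.start_idx, seg.stop_idx = 0, len(t) - 1
        seg = extrapolate_speed(seg, sig)
        assert np.array_equal(seg.extrapolated_time_s, t)
        assert np.array_equal(seg.extrapolated_speed_deg_s, v)

    def test_move_time_recovers_true_duration(self, clean_signals):
        seg = extrapolate_speed(detect_segment(clean_signals), clean_signals)
        move_time = seg.extrapolated_time_s[-1] - seg.extrapolated_time_s[0]
        assert move_time == pytest.approx(0.375, rel=0.10)


class TestComputeMetrics:
    def test_minjerk_closed_forms(self, clean_signals):
        """Peak/mean ratio of 1.875 and unit A/D-ratio are the closed-form
        signatures of the minimum-jerk speed profile."""
        m = process_trial(clean_signals)
        assert m.npa == pytest.approx(1.875, abs=0.02)
        assert m.ad_ratio == pytest.approx(1.0, abs=0.05)
        assert m.sid_pct < 1.0

    def test_time_reversed_profile_inverts_ad_ratio(self):
        p1 = TrialGenParams(300, 60, ad_asym=0.7, seed=5)
        p2 = TrialGenParams(300, 60, ad_asym=1 / 0.7, seed=5)
        m1 = process_trial(compute_signals(generate_trial(p1)))
        m2 = process_trial(compute_signals(generate_trial(p2)))
        assert m1.ad_ratio * m2.ad_ratio == pytest.approx(1.0, abs=0.1)

    def test_rom_uses_grid_boundaries(self, clean_signals):
        seg = extrapolate_speed(detect_segment(clean_signals), clean_signals)
        m = compute_metrics(clean_signals, seg)
        expected = (
            clean_signals.helical_angle_deg[seg.stop_idx]
            - clean_signals.helical_angle_deg[seg.start_idx]
        )
        assert m.rom_deg == expected

    def test_metric_invariants_on_realistic_trial(self, realistic_signals):
        m = process_trial(realistic_signals)
        assert m.peak_speed_deg_s > 0
        assert 0 < m.ttp_s < m.move_time_s
        assert m.npa >= 1
        assert m.ad_ratio > 0
        assert m.sid_pct >= 0
        assert np.isnan(m.cm) or m.cm >= 1


class TestSid:
    def _extrapolated_minjerk(self, ripple=0.0):
        from cervkin.metrics import MovementSegment

        t = np.linspace(0, 1, 101)
        v = 100 * minjerk_speed(t)
        if ripple:
            v = v + ripple * v.max() * np.sin(6 * np.pi * t) * np.sin(np.pi * t) ** 2
        seg = MovementSegment(0, 100, 50, 0.1 * v.max())
        seg.extrapolated_time_s = t
        seg.extrapolated_speed_deg_s = v
        return seg, t, v

    def test_self_fit_is_near_zero(self):
        seg, _, _ = self._extrapolated_minjerk()
        assert compute_sid(seg) < 1.0

    def test_matches_independent_quadrature_oracle(self):
        seg, t, v = self._extrapolated_minjerk(ripple=0.1)
        sid = compute_sid(seg)
        # independent oracle: explicit quadrature at the same samples
        T = t[-1] - t[0]
        A = np.trapezoid(v, t)
        vfit = (A / T) * 30 * ((t / T) ** 2) * (1 - t / T) ** 2
        rmse = np.sqrt(np.trapezoid((vfit - v) ** 2, t) / T)
        expected = 100 * rmse / (A / T)
        assert sid == pytest.approx(expected, rel=1e-9)

    def test_scale_invariance(self):
        seg, t, v = self._extrapolated_minjerk(ripple=0.07)
        sid1 = compute_sid(seg)
        seg.extrapolated_speed_deg_s = 2 * v
        assert compute_sid(seg) == pytest.approx(sid1, rel=1e-12)

    def test_peak_denominator_option(self):
        seg, t, v = self._extrapolated_minjerk(ripple=0.1)
        mean_based = compute_sid(seg, "mean")
        peak_based = compute_sid(seg, "peak")
        assert peak_based < mean_based  # peak speed exceeds mean speed


class TestConditionNumber:
    def test_collinear_vectors_capped(self):
        dirs = np.tile([0.0, 0.0, 1.0], (10, 1))
        assert compute_cm(dirs) == 1e6

    def test_matches_direct_svd_oracle(self):
        rng = np.random.default_rng(3)
        dirs = np.tile([0.0, 0.0, 1.0], (200, 1)) + rng.normal(0, 0.1, (200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        sv = np.linalg.svd(dirs, compute_uv=False)
        assert compute_cm(dirs) == pytest.approx(sv[0] / sv[2], abs=1e-9)

    def test_invariance_under_rotation_and_sign_flips(self):
        rng = np.random.default_rng(4)
        dirs = np.tile([0.0, 0.0, 1.0], (50, 1)) + rng.normal(0, 0.05, (50, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        base = compute_cm(dirs)
        Q = random_rotation(rng)
        flips = rng.choice([-1.0, 1.0], size=(50, 1))
        assert compute_cm((dirs * flips) @ Q.T) == pytest.approx(base, rel=1e-9)

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compute_cm(np.array([[0, 0, 1.0], [0, 0, 1.0]]))


class TestFlagAtypical:
    def test_normal_trial_valid(self, realistic_signals):
        m = process_trial(realistic_signals)
        assert m.valid and m.invalid_reason is None

    def test_wrong_direction_flagged(self):
        p = TrialGenParams(300, 60, direction="right", seed=2, axis_wobble_deg=1.0)
        rec = generate_trial(p)
        rec.direction = "left"  # instructed left, moved right
        m = process_trial(compute_signals(rec))
        assert not m.valid
        assert m.invalid_reason == "direction"

    def test_slow_trial_flagged(self):
        p = TrialGenParams(peak_speed_deg_s=25, rom_deg=40, seed=2)
        m = process_trial(compute_signals(generate_trial(p)))
        assert not m.valid
        assert m.invalid_reason == "low-speed"

    def test_double_peaked_profile_flagged(self):
        # two overlapping pulses: the dip between them stays above the 10%
        # segmentation threshold but falls below half the maximum
        t = np.arange(0, 1.8, 0.01)
        tau1 = np.clip((t - 0.3) / 0.5, 0, 1)
        tau2 = np.clip((t - 0.7) / 0.5, 0, 1)
        v = 100 * minjerk_speed(tau1) + 100 * minjerk_speed(tau2)
        theta = np.cumsum(v) * 0.01
        fha_t = t[::2]
        dirs = np.tile([0.0, 0.0, 1.0], (fha_t.size, 1))
        sig = KinematicSignals(
            time_s=t, helical_angle_deg=theta, angular_speed_deg_s=v,
            fha_time_s=fha_t, fha_dir=dirs, source_sample_rate_hz=60.0,
            direction="left",
        )
        seg = extrapolate_speed(detect_segment(sig), sig)
        m = compute_metrics(sig, seg)
        m = flag_atypical(m, sig, seg)
        assert not m.valid
        assert m.invalid_reason == "multi-peak"


def _mk_metrics(peak=300.0, valid=True, cm=10.0, subject="s1"):
    return TrialMetrics(
        peak_speed_deg_s=peak, rom_deg=60.0, move_time_s=0.4, ttp_s=0.2,
        npa=1.9, ad_ratio=1.0, sid_pct=10.0, cm=cm, valid=valid,
        subject_id=subject,
    )


class TestAggregateSubject:
    def test_identical_trials(self):
        agg = aggregate_subject([_mk_metrics() for _ in range(6)])
        assert agg.means["peak_speed"] == 300.0
        assert agg.n_valid_trials == 6

    def test_invalid_trials_excluded(self):
        trials = [_mk_metrics(peak=300.0)] * 5 + [_mk_metrics(peak=900.0, valid=False)]
        agg = aggregate_subject(trials)
        assert agg.means["peak_speed"] == 300.0
        assert agg.n_valid_trials == 5

    def test_mean_matches_independent_recomputation(self):
        rng = np.random.default_rng(8)
        peaks = rng.uniform(100, 500, 6)
        trials = [_mk_metrics(peak=p) for p in peaks]
        agg = aggregate_subject(trials)
        assert agg.means["peak_speed"] == pytest.approx(peaks.mean(), rel=1e-12)

    def test_reorder_invariant(self):
        rng = np.random.default_rng(9)
        trials = [_mk_metrics(peak=p) for p in rng.uniform(100, 500, 6)]
        a = aggregate_subject(trials)
        b = aggregate_subject(trials[::-1])
        assert a.means == b.means

    def test_nan_cm_handled(self):
        trials = [_mk_metrics(cm=np.nan)] * 2 + [_mk_metrics(cm=12.0)]
        agg = aggregate_subject(trials)
        assert agg.means["cm"] == 12.0

    def test_no_valid_trials_raises(self):
        with pytest.raises(ValueError, match="no valid"):
            aggregate_subject([_mk_metrics(valid=False)])
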