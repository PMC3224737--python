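"""Movement segmentation and the six per-trial kinematic variables.

Only the outward rotation is analysed.  The movement is segmented on the
100 Hz grid with a threshold of 10% of Peak Speed; because that leaves the
speed profile starting and stopping at non-zero values, each side is
extrapolated to zero with a quintic polynomial before the timing variables
are computed.  The six variables:

* **Peak Speed** (°/s) — maximum of |ω| on the 100 Hz grid;
* **ROM** (°) — helical-angle difference between segment stop and start;
* **NPA** — Peak Speed / mean speed of the extrapolated profile (1.875 for
  an ideal minimum-jerk profile);
* **A/D-ratio** — acceleration time over deceleration time,
  TTP / (Move Time − TTP);
* **SID** (%) — normalised RMS deviation of the extrapolated speed profile
  from a duration- and displacement-matched minimum-jerk profile;
* **CM** (a.u.) — condition number (σ_max/σ_min) of the finite-helical-axis
  direction vectors within the segment; a *small* value means the rotation
  axis wandered *more* (more conjunct movement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .kinematics import KinematicSignals, align_axis_signs

__all__ = [
    "MovementSegment",
    "TrialMetrics",
    "SubjectMetrics",
    "SegmentationError",
    "detect_segment",
    "extrapolate_speed",
    "compute_metrics",
    "compute_sid",
    "compute_cm",
    "flag_atypical",
    "aggregate_subject",
    "process_trial",
    "METRIC_NAMES",
]

METRIC_NAMES = ("peak_speed", "rom", "npa", "ad_ratio", "sid", "cm")

CM_DEGENERATE_CAP = 1e6
_MAX_EXTENSION_S = 0.25


class SegmentationError(ValueError):
    """The speed profile cannot be segmented (truncated or unterminated)."""


@dataclass
class MovementSegment:
    """Outward-rotation segment on the 100 Hz grid, plus the zero-extended
    speed profile used for the timing variables."""

    start_idx: int
    stop_idx: int
    peak_idx: int
    threshold_deg_s: float
    extrapolated_time_s: Optional[np.ndarray] = None
    extrapolated_speed_deg_s: Optional[np.ndarray] = None


@dataclass
class TrialMetrics:
    peak_speed_deg_s: float
    rom_deg: float
    move_time_s: float
    ttp_s: float
    npa: float
    ad_ratio: float
    sid_pct: float
    cm: float  # NaN if too little defined axis data
    valid: bool = True
    invalid_reason: Optional[str] = None
    subject_id: str = ""
    trial_index: int = 1
    direction: str = "left"


@dataclass
class SubjectMetrics:
    """Per-variable means over a subject's valid trials, left/right pooled."""

    subject_id: str
    session: str
    means: dict[str, float] = field(default_factory=dict)
    n_valid_trials: int = 0


def detect_segment(signals: KinematicSignals) -> MovementSegment:
    """Locate the outward rotation: start/stop at the last/first samples at or
    below 10% of Peak Speed before/after the speed maximum."""
    v = signals.angular_speed_deg_s
    peak = int(np.argmax(v))
    if peak == 0 or peak == v.size - 1:
        raise SegmentationError("speed peak at series boundary: truncated trial")
    thr = 0.1 * v[peak]
    below_before = np.nonzero(v[:peak] <= thr)[0]
    if below_before.size == 0:
        raise SegmentationError("speed never below threshold before peak: truncated trial")
    start = int(below_before[-1])
    below_after = np.nonzero(v[peak + 1 :] <= thr)[0]
    if below_after.size == 0:
        raise SegmentationError("speed never drops below threshold after peak: unterminated movement")
    stop = int(peak + 1 + below_after[0])
    return MovementSegment(start_idx=start, stop_idx=stop, peak_idx=peak, threshold_deg_s=thr)


def _quintic_extension(
    t0: float, v0: float, v1: float, v2: float, te: float, h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Quintic p on [te, t0] with p(te)=p'(te)=p''(te)=0 and matching value and
    first/second derivative at the boundary t0; sampled at spacing h from te."""
    # Work in s = t - te so the Vandermonde system is well scaled.
    L = t0 - te
    A = np.zeros((6, 6))
    b = np.array([0.0, 0.0, 0.0, v0, v1, v2])
    powers = np.arange(6)
    A[0, 0] = 1.0  # p(0)=0
    A[1, 1] = 1.0  # p'(0)=0
    A[2, 2] = 2.0  # p''(0)=0
    A[3] = L ** powers
    A[4] = powers * L ** np.maximum(powers - 1, 0)
    A[5] = powers * np.maximum(powers - 1, 0) * L ** np.maximum(powers - 2, 0)
    coef = np.linalg.solve(A, b)
    s = np.arange(0.0, L, h)
    vals = np.polyval(coef[::-1], s)
    return te + s, np.maximum(vals, 0.0)


def _boundary_fit(
    t: np.ndarray, v: np.ndarray, idx: int, side: str, window_s: float = 0.03
) -> tuple[float, float, float]:
    """Endpoint offset and smoothed boundary derivatives from the profile
    history just inside the segment.

    Over a short window, a least-squares quadratic in v and a least-squares
    line in √v are both extended to their zero crossing beyond the boundary.
    For bell-shaped tails (v ≈ c·δ² near rest) the quadratic-in-v estimate
    lands short of the true rest point and the √v estimate beyond it, so a
    weighted mean of the two is used (0.4/0.6, calibrated against the
    analytic minimum-jerk tail over the 100–500 °/s speed range); a negative
    boundary slope in either model is treated as wrong-sign (NaN offset →
    linear fallback upstream).  Returns (delta, d1, d2) with delta ≥ 0 the
    offset to the new endpoint and d1, d2 the fitted first/second derivative
    at the boundary in the into-segment time direction.
    """
    h = float(np.mean(np.diff(t)))
    k = max(int(round(window_s / h)), 3)
    if side == "start":
        sl = slice(idx, min(idx + k + 1, v.size))
        x = t[sl] - t[idx]
    else:
        sl = slice(max(idx - k, 0), idx + 1)
        x = t[idx] - t[sl]
    vw = np.maximum(v[sl], 0.0)
    c2, c1, c0 = np.polyfit(x, vw, 2)
    est_quad = est_sqrt = None
    if c1 > 0:  # quadratic zero at x < 0
        disc = c1 * c1 - 4 * c2 * c0
        if abs(c2) < 1e-12:
            est_quad = c0 / c1
        elif disc >= 0:
            roots = np.array([(-c1 - np.sqrt(disc)) / (2 * c2),
                              (-c1 + np.sqrt(disc)) / (2 * c2)])
            neg = -roots[roots < 0]
            if neg.size:
                est_quad = float(neg.min())
        else:
            est_quad = c0 / c1  # tangent fallback
    b1, b0 = np.polyfit(x, np.sqrt(vw), 1)
    if b1 > 0 and b0 > 0:
        est_sqrt = float(b0 / b1)
    if est_quad is None and est_sqrt is None:
        return np.nan, float(c1), float(2 * c2)
    if est_quad is not None and est_sqrt is not None:
        delta = 0.4 * est_quad + 0.6 * est_sqrt
    else:
        delta = est_quad if est_quad is not None else est_sqrt
    return float(min(delta, _MAX_EXTENSION_S)), float(c1), float(2 * c2)


def extrapolate_speed(seg: MovementSegment, signals: KinematicSignals) -> MovementSegment:
    """Extend the segmented speed profile to zero on both sides.

    On each side a quintic polynomial matches the profile's value and first
    and second derivative at the segment boundary and lands at zero speed and
    slope (and curvature) at a new endpoint, placed where a quadratic
    extension of the boundary slope reaches zero (at most 0.25 s beyond the
    boundary).  A boundary slope of the wrong sign falls back to a linear
    ramp to zero with a warning.
    """
    t = signals.time_s
    v = signals.angular_speed_deg_s
    h = float(np.mean(np.diff(t)))
    s, p = seg.start_idx, seg.stop_idx

    pieces_t: list[np.ndarray] = []
    pieces_v: list[np.ndarray] = []

    # --- start side (extend backwards; toward zero means slope rising forward)
    v0 = float(v[s])
    if v0 <= 0.0:
        pass  # already at zero: no extension
    else:
        delta, d1, d2 = _boundary_fit(t, v, s, "start")
        if np.isnan(delta):
            warnings.warn("speed not rising at segment start; linear extension used")
            te = t[s] - _MAX_EXTENSION_S
            ts = np.arange(te, t[s] - 1e-12, h)
            vs = v0 * (ts - te) / (t[s] - te)
        else:
            te = t[s] - delta
            ts, vs = _quintic_extension(t[s], v0, d1, d2, te, h)
        if ts.size:
            vs[0] = 0.0
            pieces_t.append(ts)
            pieces_v.append(vs)

    pieces_t.append(t[s : p + 1])
    pieces_v.append(v[s : p + 1])

    # --- stop side (extend forwards; speed falling, mirror in time)
    v0 = float(v[p])
    if v0 > 0.0:
        # fitted derivatives are in the into-segment direction, i.e. already
        # in the mirrored time u = -t used for the quintic below
        delta, d1, d2 = _boundary_fit(t, v, p, "stop")
        if np.isnan(delta):
            warnings.warn("speed not falling at segment stop; linear extension used")
            te = t[p] + _MAX_EXTENSION_S
            ts = np.arange(te, t[p] + 1e-12, -h)[::-1]
            vs = v0 * (te - ts) / (te - t[p])
        else:
            te = t[p] + delta
            ts_rev, vs_rev = _quintic_extension(-t[p], v0, d1, d2, -te, h)
            ts, vs = -ts_rev[::-1], vs_rev[::-1]
        if ts.size:
            vs[-1] = 0.0
            pieces_t.append(ts)
            pieces_v.append(vs)

    seg.extrapolated_time_s = np.concatenate(pieces_t)
    seg.extrapolated_speed_deg_s = np.concatenate(pieces_v)
    return seg


def compute_sid(seg: MovementSegment, denominator: str = "mean") -> float:
    """Speed index of deviation from the minimum-jerk model, in percent.

    A minimum-jerk speed profile v(τ) = (A/T)(30τ² − 60τ³ + 30τ⁴) with
    T = extrapolated Move Time and A = time-integral of the extrapolated
    speed (displacement-matched, parameter-free) is compared with the
    extrapolated observed profile; SID = 100 · time-weighted RMSE /
    mean (or peak) observed speed.
    """
    if seg.extrapolated_time_s is None:
        raise ValueError("segment must be extrapolated first")
    t = seg.extrapolated_time_s
    v = seg.extrapolated_speed_deg_s
    T = t[-1] - t[0]
    A = float(np.trapezoid(v, t))
    if A <= 0:
        raise ValueError("zero displacement: SID undefined")
    tau = (t - t[0]) / T
    v_fit = (A / T) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    rmse = float(np.sqrt(np.trapezoid((v_fit - v) ** 2, t) / T))
    if denominator == "mean":
        denom = A / T
    elif denominator == "peak":
        denom = float(v.max())
    else:
        raise ValueError(f"unknown SID denominator {denominator!r}")
    return 100.0 * rmse / denom


def compute_cm(fha_dirs: np.ndarray) -> float:
    """Condition number σ_max/σ_min of the (sign-aligned) FHA direction set.

    Degenerate, perfectly collinear clouds (σ_min ≈ 0) are capped at 1e6.
    Fewer than 3 defined directions raise, flagging the trial invalid for CM
    only.
    """
    dirs = np.asarray(fha_dirs, float)
    dirs = dirs[~np.isnan(dirs).any(axis=1)]
    if dirs.shape[0] < 3:
        raise ValueError("need at least 3 defined axis directions for CM")
    dirs = align_axis_signs(dirs)
    sv = np.linalg.svd(dirs, compute_uv=False)
    if sv[-1] < 1e-12:
        return CM_DEGENERATE_CAP
    return float(min(sv[0] / sv[-1], CM_DEGENERATE_CAP))


def compute_metrics(
    signals: KinematicSignals,
    seg: MovementSegment,
    sid_denominator: str = "mean",
) -> TrialMetrics:
    """Assemble all six variables (plus Move Time and TTP) for one trial.

    ROM uses helical angle at the segment boundaries on the 100 Hz grid;
    the extrapolated profile drives Move Time, TTP, NPA, A/D-ratio and SID.
    """
    if seg.extrapolated_time_s is None:
        raise ValueError("segment must be extrapolated first")
    t_ext = seg.extrapolated_time_s
    v_ext = seg.extrapolated_speed_deg_s
    peak_speed = float(signals.angular_speed_deg_s[seg.peak_idx])
    t_peak = float(signals.time_s[seg.peak_idx])
    move_time = float(t_ext[-1] - t_ext[0])
    ttp = float(t_peak - t_ext[0])
    if not 0 < ttp < move_time:
        raise ValueError("inconsistent segment: peak outside extrapolated profile")
    mean_speed = float(np.trapezoid(v_ext, t_ext)) / move_time
    rom = float(
        signals.helical_angle_deg[seg.stop_idx] - signals.helical_angle_deg[seg.start_idx]
    )
    sid = compute_sid(seg, denominator=sid_denominator)
    in_seg = (signals.fha_time_s >= signals.time_s[seg.start_idx]) & (
        signals.fha_time_s <= signals.time_s[seg.stop_idx]
    )
    try:
        cm = compute_cm(signals.fha_dir[in_seg])
    except ValueError:
        cm = np.nan
    return TrialMetrics(
        peak_speed_deg_s=peak_speed,
        rom_deg=rom,
        move_time_s=move_time,
        ttp_s=ttp,
        npa=peak_speed / mean_speed,
        ad_ratio=ttp / (move_time - ttp),
        sid_pct=sid,
        cm=cm,
        subject_id=signals.subject_id,
        trial_index=signals.trial_index,
        direction=signals.direction,
    )


def _net_rotation_sign(signals: KinematicSignals, seg: MovementSegment) -> float:
    """Sign of the net axial (z) rotation inside the segment, from the raw
    (un-aligned) FHA directions, whose signs encode the rotation sense."""
    in_seg = (signals.fha_time_s >= signals.time_s[seg.start_idx]) & (
        signals.fha_time_s <= signals.time_s[seg.stop_idx]
    )
    dirs = signals.fha_dir[in_seg]
    dirs = dirs[~np.isnan(dirs).any(axis=1)]
    if dirs.shape[0] == 0:
        return 0.0
    return float(np.sign(dirs[:, 2].mean()))


def flag_atypical(
    metrics: TrialMetrics,
    signals: KinematicSignals,
    seg: MovementSegment,
    min_peak_speed: float = 30.0,
    min_rom: float = 10.0,
) -> TrialMetrics:
    """Automated stand-in for manual curation of atypical trials.

    A trial is flagged invalid when the rotation is implausibly slow or
    small, performed opposite the instructed direction (left = positive
    rotation about the vertical axis), or shows a clearly multi-peaked speed
    profile (two near-maximal peaks separated by a drop below half maximum).
    """
    reason = None
    if metrics.peak_speed_deg_s < min_peak_speed:
        reason = "low-speed"
    elif metrics.rom_deg < min_rom:
        reason = "low-rom"
    else:
        sign = _net_rotation_sign(signals, seg)
        expected = 1.0 if metrics.direction == "left" else -1.0
        if sign != 0.0 and sign != expected:
            reason = "direction"
        else:
            v = signals.angular_speed_deg_s[seg.start_idx : seg.stop_idx + 1]
            vmax = v.max()
            peaks, _ = find_peaks(v, height=0.8 * vmax)
            if peaks.size >= 2:
                for a, b in zip(peaks[:-1], peaks[1:]):
                    if v[a:b + 1].min() < 0.5 * vmax:
                        reason = "multi-peak"
                        break
    if reason is not None:
        metrics.valid = False
        metrics.invalid_reason = reason
    return metrics


def process_trial(
    signals: KinematicSignals, sid_denominator: str = "mean"
) -> TrialMetrics:
    """Segment, extrapolate, compute and flag one trial's metrics."""
    seg = detect_segment(signals)
    seg = extrapolate_speed(seg, signals)
    m = compute_metrics(signals, seg, sid_denominator=sid_denominator)
    return flag_atypical(m, signals, seg)


def aggregate_subject(
    trials: list[TrialMetrics], session: str = "test1"
) -> SubjectMetrics:
    """Mean per variable over valid trials, left and right rotations pooled.

    CM is averaged over the trials where it is defined (a trial can be valid
    overall yet lack enough axis data for CM).
    """
    valid = [m for m in trials if m.valid]
    if not valid:
        raise ValueError("no valid trials to aggregate")
    means = {
        "peak_speed": float(np.mean([m.peak_speed_deg_s for m in valid])),
        "rom": float(np.mean([m.rom_deg for m in valid])),
        "npa": float(np.mean([m.npa for m in valid])),
        "ad_ratio": float(np.mean([m.ad_ratio for m in valid])),
        "sid": float(np.mean([m.sid_pct for m in valid])),
        "move_time": float(np.mean([m.move_time_s for m in valid])),
        "ttp": float(np.mean([m.ttp_s for m in valid])),
    }
    cms = np.array([m.cm for m in valid], float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means["cm"] = float(np.nanmean(cms)) if np.isfinite(cms).any() else np.nan
    return SubjectMetrics(
        subject_id=valid[0].subject_id,
        session=session,
        means=means,
        n_valid_trials=len(valid),
    )
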