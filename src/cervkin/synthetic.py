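"""Synthetic fast axial-rotation trials and cohorts.

The generator emulates the fast cervical axial-rotation protocol: seated
subjects rotate the head "as fast as possible" to one side, six trials in
alternating directions, recorded by two 6-DOF receivers at 60 Hz.  The
primary rotation angle follows a time-warped minimum-jerk trajectory (the
warp exponent shifts the speed peak to produce acceleration/deceleration
asymmetry), with a band-limited sinusoidal speed ripple (jerkiness), a
slowly precessing rotation axis within a cone about the vertical (conjunct
movement), additive Gaussian orientation sensor noise, and 0.5 s of
stationary padding on both sides so segmentation sees sub-threshold speed.

Cohort defaults reproduce the published group-level study conditions:
Peak Speed 348 ± 92 °/s (controls, CON) vs 226 ± 88 °/s (patients, NS),
ROM ≈ 61.5 ± 8.3 vs 52.7 ± 9.2°, with ripple and axis-wobble levels
calibrated so the smoothness (SID) and axis-dispersion (CM) variables land
in their published ranges, a negative age trend on speed and range, and a
low-back-pain comorbidity flag for roughly half of the patient group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .kinematics import matrix_to_euler_zyx
from .trial_io import (
    QUESTIONNAIRE_SCHEMA,
    CohortDataset,
    RawTrialRecording,
    SubjectRecord,
)

__all__ = [
    "TrialGenParams",
    "GroupConfig",
    "CohortGenConfig",
    "generate_trial",
    "generate_cohort",
    "generate_questionnaire_block",
    "minjerk_position",
    "minjerk_speed",
    "calibrate_wobble_to_cm",
]

_PAD_S = 0.5


def minjerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position x(τ) = 10τ³ − 15τ⁴ + 6τ⁵."""
    tau = np.asarray(tau, float)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minjerk_speed(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk speed dx/dτ = 30τ²(1 − τ)²; peak 1.875 at τ=½."""
    tau = np.asarray(tau, float)
    return 30 * tau**2 * (1 - tau) ** 2


@dataclass(frozen=True)
class TrialGenParams:
    """Ground-truth parameters of one generated trial.

    ``ad_asym`` is the target acceleration/deceleration time ratio (1 =
    symmetric profile); ``ripple_frac`` scales a band-limited sinusoidal
    speed perturbation as a fraction of peak speed; ``axis_wobble_deg`` is
    the cone half-angle of the slow random-walk precession of the rotation
    axis; ``sensor_noise_deg`` is the per-channel orientation noise SD.
    """

    peak_speed_deg_s: float = 300.0
    rom_deg: float = 60.0
    ad_asym: float = 1.0
    ripple_frac: float = 0.0
    axis_wobble_deg: float = 0.0
    sensor_noise_deg: float = 0.0
    sample_rate_hz: float = 60.0
    direction: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rom_deg <= 0 or self.peak_speed_deg_s <= 0:
            raise ValueError("rom and peak speed must be positive")
        if self.ad_asym <= 0:
            raise ValueError("ad_asym must be positive")
        if min(self.ripple_frac, self.axis_wobble_deg, self.sensor_noise_deg) < 0:
            raise ValueError("noise parameters must be non-negative")


def _asym_minjerk_position(tau: np.ndarray, tau_p: float) -> np.ndarray:
    """Normalised position of a two-piece minimum-jerk movement whose speed
    peak sits at phase ``tau_p``: each side is half a minimum-jerk bell,
    compressed/stretched in time.  The speed profile is continuous with peak
    value 1.875 (so NPA is exactly 1.875 for every asymmetry) and the
    acceleration/deceleration time ratio is exactly τ_p/(1 − τ_p)."""
    tau = np.asarray(tau, float)
    accel = tau <= tau_p
    out = np.empty_like(tau)
    u1 = tau[accel] / (2 * tau_p)
    out[accel] = 2 * tau_p * minjerk_position(u1)
    u2 = 0.5 + (tau[~accel] - tau_p) / (2 * (1 - tau_p))
    out[~accel] = tau_p + 2 * (1 - tau_p) * (minjerk_position(u2) - 0.5)
    return out


def _wobble_path(progress: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS smooth random arc over movement progress ∈ [0, 1]: one- and
    two-cycle sinusoids with random amplitudes and phases."""
    a1, a2 = rng.standard_normal(2)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    w = a1 * np.sin(2 * np.pi * progress + ph1) + 0.6 * a2 * np.sin(
        4 * np.pi * progress + ph2
    )
    rms = np.sqrt(np.mean((a1 * np.sin(2 * np.pi * np.linspace(0, 1, 200) + ph1)
                           + 0.6 * a2 * np.sin(4 * np.pi * np.linspace(0, 1, 200) + ph2)) ** 2))
    return w / rms if rms > 0 else w


def generate_trial(p: TrialGenParams) -> RawTrialRecording:
    """Generate one trial's raw two-receiver recording from ground truth.

    The head-on-thorax rotation is Rot(n(t), ±θ(t)) with θ a (warped)
    minimum-jerk trajectory of amplitude ``rom_deg`` plus windowed ripple,
    and n(t) a unit axis precessing about vertical.  The thorax is held at
    identity; both receivers' cardan channels then receive additive Gaussian
    noise.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(p.seed)
    fs = p.sample_rate_hz
    tau_p = p.ad_asym / (1.0 + p.ad_asym)

    # the two-piece profile peaks at 1.875/T regardless of asymmetry
    T = 1.875 * p.rom_deg / p.peak_speed_deg_s

    n_pad = int(round(_PAD_S * fs))
    n_move = max(int(round(T * fs)), 8)
    n_total = n_move + 2 * n_pad + 1
    t = np.arange(n_total) / fs
    t_move_start = n_pad / fs

    tau = np.clip((t - t_move_start) / T, 0.0, 1.0)
    theta = p.rom_deg * _asym_minjerk_position(tau, tau_p)

    if p.ripple_frac > 0:
        freqs = (5.0, 7.0, 9.0)
        # window vanishes at the movement ends *and* at the speed peak, so
        # the labelled peak speed remains the trial's true peak speed
        window = np.where(
            tau <= tau_p,
            np.sin(np.pi * tau / tau_p) ** 2,
            np.sin(np.pi * (tau - tau_p) / (1 - tau_p)) ** 2,
        )
        for f in freqs:
            amp_angle = p.ripple_frac * p.peak_speed_deg_s / (len(freqs) * 2 * np.pi * f)
            phase = rng.uniform(0, 2 * np.pi)
            theta = theta + amp_angle * np.sin(2 * np.pi * f * t + phase) * window

    # axis precession: a smooth random arc through the wobble cone,
    # parameterised by movement progress so the axis is stationary whenever
    # the head is (no spurious speed in the padding or the profile tails)
    x_prog = _asym_minjerk_position(tau, tau_p)
    if p.axis_wobble_deg > 0:
        scale = np.tan(np.radians(p.axis_wobble_deg))
        wx = _wobble_path(x_prog, rng) * scale
        wy = _wobble_path(x_prog, rng) * scale
    else:
        wx = np.zeros(n_total)
        wy = np.zeros(n_total)
    axes = np.column_stack([wx, wy, np.ones(n_total)])
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)

    sign = 1.0 if p.direction == "left" else -1.0
    ang = np.radians(sign * theta)
    K = np.zeros((n_total, 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axes[:, 2], axes[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axes[:, 2], -axes[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axes[:, 1], axes[:, 0]
    I = np.eye(3)
    R = (
        I[None]
        + np.sin(ang)[:, None, None] * K
        + (1 - np.cos(ang))[:, None, None] * (K @ K)
    )

    head_euler = matrix_to_euler_zyx(R)
    thorax_euler = np.zeros((n_total, 3))
    if p.sensor_noise_deg > 0:
        head_euler = head_euler + rng.normal(0, p.sensor_noise_deg, head_euler.shape)
        thorax_euler = thorax_euler + rng.normal(0, p.sensor_noise_deg, thorax_euler.shape)

    if np.any(np.abs(head_euler[:, 1]) > 80.0):
        warnings.warn("elevation guard hit; regenerating with reduced axis wobble")
        return generate_trial(replace(p, axis_wobble_deg=p.axis_wobble_deg / 2))

    head_pos = np.tile([0.0, 0.0, 0.35], (n_total, 1)) + rng.normal(0, 1e-3, (n_total, 3))
    thorax_pos = rng.normal(0, 1e-3, (n_total, 3))

    return RawTrialRecording(
        subject_id="synthetic",
        trial_index=1,
        direction=p.direction,
        sample_rate_hz=fs,
        time_s=t,
        head_euler_deg=head_euler,
        head_pos=head_pos,
        thorax_euler_deg=thorax_euler,
        thorax_pos=thorax_pos,
    )


@dataclass(frozen=True)
class GroupConfig:
    """Latent parameter distributions (mean, SD) for one group."""

    n: int
    peak_speed: tuple[float, float]
    rom: tuple[float, float]
    ad_ratio: tuple[float, float]
    ripple_frac: tuple[float, float]
    axis_wobble_deg: tuple[float, float]
    age: tuple[float, float]
    low_back_pain_prob: float = 0.0


@dataclass(frozen=True)
class CohortGenConfig:
    """Study-conditions configuration of a synthetic cohort.

    Defaults match the published pooled-cohort group parameters for Peak
    Speed and ROM, asymmetry at the published A/D-ratio levels, ripple and
    wobble calibrated to the published SID and CM ranges, and group age
    distributions with a negative age trend on speed and range.  Session
    means for a retest cohort share the subject latents, perturbed by a
    between-session component (``between_session_cv`` of the subject mean);
    individual trials jitter around the session mean by ``trial_cv``.
    """

    con: GroupConfig = GroupConfig(
        n=49,
        peak_speed=(348.0, 92.0),
        rom=(61.5, 8.3),
        ad_ratio=(0.81, 0.24),
        ripple_frac=(0.025, 0.010),
        axis_wobble_deg=(1.55, 0.35),
        age=(46.0, 10.0),
    )
    ns: GroupConfig = GroupConfig(
        n=118,
        peak_speed=(226.0, 88.0),
        rom=(52.7, 9.2),
        ad_ratio=(0.74, 0.22),
        ripple_frac=(0.06, 0.02),
        axis_wobble_deg=(1.38, 0.3),
        age=(50.5, 9.0),
        low_back_pain_prob=62.0 / 118.0,
    )
    sessions: int = 1
    trials_per_session: int = 6
    between_session_cv: float = 0.10
    trial_cv: float = 0.08
    #: white orientation jitter SD; the tracker's (larger) quasi-static field
    #: distortion error barely affects differentiated kinematics and is not
    #: modelled
    sensor_noise_deg: float = 0.03
    age_slope_peak: float = -3.0  # °/s per year about the group mean age
    age_slope_rom: float = -0.45  # ° per year
    seed: int = 0


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if not lo <= mean <= hi:
        raise ValueError(f"unsatisfiable truncation: mean {mean} outside [{lo}, {hi}]")
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError("unsatisfiable truncation: acceptance too low")


def generate_cohort(cfg: CohortGenConfig = CohortGenConfig()) -> CohortDataset:
    """Draw subject latents from the group distributions and synthesise all
    trials (6 per session, alternating direction, half the cohort starting
    rightward).  The returned dataset carries a ``latents`` table with each
    subject's ground-truth session means."""
    rng = np.random.default_rng(cfg.seed)
    subjects: list[SubjectRecord] = []
    recordings: list[RawTrialRecording] = []
    latent_rows = []
    sessions = [f"test{k + 1}" for k in range(cfg.sessions)]
    sid_counter = 0
    for group_name, gc in (("CON", cfg.con), ("NS", cfg.ns)):
        # part of the configured between-subject SD is carried by the age trend
        slope_p, slope_r = cfg.age_slope_peak, cfg.age_slope_rom
        resid_sd_peak = np.sqrt(max(gc.peak_speed[1] ** 2 - (slope_p * gc.age[1]) ** 2, 25.0))
        resid_sd_rom = np.sqrt(max(gc.rom[1] ** 2 - (slope_r * gc.age[1]) ** 2, 1.0))
        for i in range(gc.n):
            sid_counter += 1
            sid = f"{group_name}{sid_counter:03d}"
            age = _trunc_normal(rng, gc.age[0], gc.age[1], 20.0, 70.0)
            peak = _trunc_normal(
                rng,
                gc.peak_speed[0] + slope_p * (age - gc.age[0]),
                resid_sd_peak,
                60.0,
                700.0,
            )
            rom = _trunc_normal(
                rng, gc.rom[0] + slope_r * (age - gc.age[0]), resid_sd_rom, 25.0, 85.0
            )
            ad = _trunc_normal(rng, gc.ad_ratio[0], gc.ad_ratio[1], 0.3, 2.5)
            ripple = _trunc_normal(rng, gc.ripple_frac[0], gc.ripple_frac[1], 0.005, 0.35)
            wobble = _trunc_normal(
                rng, gc.axis_wobble_deg[0], gc.axis_wobble_deg[1], 0.4, 8.0
            )
            lbp: Optional[bool] = None
            if group_name == "NS":
                lbp = bool(rng.random() < gc.low_back_pain_prob)
            start_right = i % 2 == 1
            for session in sessions:
                bs = rng.normal(1.0, cfg.between_session_cv) if cfg.sessions > 1 else 1.0
                bs = max(bs, 0.5)
                sess_peak = peak * bs
                sess_rom = rom * max(rng.normal(1.0, cfg.between_session_cv / 2), 0.6) if cfg.sessions > 1 else rom
                subjects.append(
                    SubjectRecord(
                        subject_id=sid,
                        group=group_name,
                        age_years=age,
                        low_back_pain=lbp,
                        session=session,
                    )
                )
                latent_rows.append(
                    {
                        "subject_id": sid,
                        "session": session,
                        "group": group_name,
                        "age": age,
                        "peak_speed": sess_peak,
                        "rom": sess_rom,
                        "ad_ratio": ad,
                        "ripple_frac": ripple,
                        "axis_wobble_deg": wobble,
                        "low_back_pain": lbp,
                    }
                )
                for trial in range(1, cfg.trials_per_session + 1):
                    right = (trial % 2 == 1) == start_right
                    params = TrialGenParams(
                        peak_speed_deg_s=max(
                            sess_peak * rng.normal(1.0, cfg.trial_cv), 40.0
                        ),
                        rom_deg=float(
                            np.clip(sess_rom * rng.normal(1.0, cfg.trial_cv / 2), 20.0, 90.0)
                        ),
                        ad_asym=float(np.clip(ad * rng.normal(1.0, cfg.trial_cv), 0.25, 3.0)),
                        ripple_frac=ripple,
                        axis_wobble_deg=wobble,
                        sensor_noise_deg=cfg.sensor_noise_deg,
                        direction="right" if right else "left",
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    rec = generate_trial(params)
                    rec.subject_id = sid
                    rec.trial_index = trial
                    rec.session = session
                    recordings.append(rec)
    ds = CohortDataset(subjects=subjects, recordings=recordings)
    ds.latents = pd.DataFrame(latent_rows)
    return ds


#: Six-level items use the full schema minus the continuous totals and age.
_CONTINUOUS_PREDICTORS = {
    "tsk": (33.0, 13.0),
    "sf36_pf": (70.0, 20.0),
    "sf36_bp": (50.0, 20.0),
    "sf36_gh": (60.0, 20.0),
    "sf36_vt": (50.0, 20.0),
    "sf36_sf": (70.0, 22.0),
    "sf36_mh": (70.0, 18.0),
    "dash_1_19": (25.0, 15.0),
    "symptom_duration": (120.0, 80.0),
}


def generate_questionnaire_block(
    cohort: CohortDataset,
    n_informative: int = 3,
    effect_r: float = -0.35,
    seed: int = 0,
    session: str = "test1",
) -> tuple[pd.DataFrame, list[str]]:
    """Attach a 44-predictor self-rating block to the cohort's subjects.

    ``n_informative`` predictors are generated from a Gaussian copula with
    correlation ``effect_r`` to each subject's latent Peak Speed; continuous
    totals stay Gaussian on their instrument scales, six-level items are
    quantile-discretised to 1..6, and about 2% of cells (never age) are set
    missing.  Returns the subject table and the informative predictor names.
    """
    if abs(effect_r) >= 1:
        raise ValueError("|effect_r| must be < 1")
    latents = getattr(cohort, "latents", None)
    if latents is None:
        raise ValueError("cohort carries no ground-truth latents")
    rng = np.random.default_rng(seed)
    lat = latents[latents["session"] == session].reset_index(drop=True)
    n = len(lat)
    z_y = (lat["peak_speed"] - lat["peak_speed"].mean()) / lat["peak_speed"].std(ddof=1)
    z_y = z_y.to_numpy()

    names = [q for q in QUESTIONNAIRE_SCHEMA if q != "age"]
    informative = list(rng.choice([q for q in names], size=n_informative, replace=False))
    data: dict[str, np.ndarray] = {}
    for name in names:
        if name in informative:
            z = effect_r * z_y + np.sqrt(1 - effect_r**2) * rng.standard_normal(n)
        else:
            z = rng.standard_normal(n)
        if name in _CONTINUOUS_PREDICTORS:
            mu, sd = _CONTINUOUS_PREDICTORS[name]
            data[name] = mu + sd * z
        else:
            # six-level scale by quantile discretisation of the latent Gaussian
            from scipy.stats import norm

            edges = norm.ppf(np.linspace(0, 1, 7)[1:-1])
            data[name] = (np.digitize(z, edges) + 1).astype(float)
    df = pd.DataFrame(data)
    # ~2% missingness at random
    mask = rng.random(df.shape) < 0.02
    df = df.mask(mask)
    df.insert(0, "age", lat["age"].to_numpy())
    df.insert(0, "low_back_pain", lat["low_back_pain"].to_numpy())
    df.insert(0, "group", lat["group"].to_numpy())
    df.insert(0, "subject_id", lat["subject_id"].to_numpy())
    return df, informative


def calibrate_wobble_to_cm(
    wobble_grid: np.ndarray,
    n_trials: int = 10,
    seed: int = 0,
    base: TrialGenParams = TrialGenParams(ripple_frac=0.1, sensor_noise_deg=0.15),
) -> pd.DataFrame:
    """Empirical map from axis-wobble cone angle to the measured axis
    condition number CM (no closed form exists for a noisy axis cloud)."""
    from .kinematics import compute_signals
    from .metrics import process_trial

    rng = np.random.default_rng(seed)
    rows = []
    for w in np.asarray(wobble_grid, float):
        cms = []
        for _ in range(n_trials):
            p = replace(base, axis_wobble_deg=float(w), seed=int(rng.integers(0, 2**31 - 1)))
            m = process_trial(compute_signals(generate_trial(p)))
            if np.isfinite(m.cm):
                cms.append(m.cm)
        rows.append(
            {"axis_wobble_deg": w, "cm_mean": float(np.mean(cms)), "cm_sd": float(np.std(cms))}
        )
    return pd.DataFrame(rows)
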