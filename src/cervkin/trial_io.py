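"""Data model and file dialects for raw rotation-trial recordings.

A trial is one fast axial head rotation recorded with a two-receiver
electromagnetic tracker (forehead and upper-thoracic receivers), each sample
holding ZYX cardan (azimuth-elevation-roll) orientation angles in degrees and
a Cartesian position, nominally sampled at 60 Hz.  Trials are stored one per
CSV file; a JSON manifest links trial files to a subject table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DialectConfig",
    "RawTrialRecording",
    "SubjectRecord",
    "CohortDataset",
    "FormatError",
    "ValidationError",
    "LinkageError",
    "read_recording",
    "write_recording",
    "load_cohort",
    "QUESTIONNAIRE_SCHEMA",
]


class FormatError(ValueError):
    """A file does not match the declared dialect (missing/extra channels)."""


class ValidationError(ValueError):
    """A recording or cohort violates a structural invariant."""


class LinkageError(ValueError):
    """A manifest entry cannot be resolved against the subject table."""


#: Canonical CSV column order: time, head azimuth/elevation/roll (deg),
#: head x/y/z, thorax azimuth/elevation/roll (deg), thorax x/y/z.
CSV_COLUMNS = (
    "t",
    "haz", "hel", "hro", "hx", "hy", "hz",
    "taz", "tel", "tro", "tx", "ty", "tz",
)

#: The 44 self-rated predictors used by the association model: questionnaire
#: totals/subscales, single neck-disability and arm items, and additional
#: six-level symptom/function questions.
QUESTIONNAIRE_SCHEMA = (
    # totals / index scores
    "tsk", "sf36_pf", "sf36_bp", "sf36_gh", "sf36_vt", "sf36_sf", "sf36_mh",
    "dash_1_19",
    # single neck-disability items
    "pain_intensity", "headache", "concentration_difficulties",
    "sleeping_disturbance", "car_driving",
    # single arm/shoulder/hand items
    "arm_shoulder_hand_pain", "tingling_arm_shoulder_hand",
    "weakness_arm_shoulder_hand",
    # additional questions (six-level scale unless continuous)
    "age", "symptom_duration", "physical_activity",
    "bend_head_forward", "bend_head_backward",
    "bend_head_right", "bend_head_left",
    "turn_head_right", "turn_head_left", "run",
    "jaw_disorder", "difficulty_swallowing", "clumsiness_hands",
    "dizziness", "balance_disturbance", "sensory_disturbance",
    "sensitivity_light", "sensitivity_sound", "nausea",
    "neck_pain_activity", "neck_pain_rest", "neck_stiffness",
    "neck_tenderness", "neck_tension", "neck_fatigue",
    "neck_weakness", "neck_crepitations", "neck_lockings",
)


@dataclass(frozen=True)
class DialectConfig:
    """Declared CSV conventions of a tracker export.

    The tracker's Euler sign conventions are not universal, so the dialect
    lets users declare per-axis sign flips (applied on read) for the three
    angle channels of each receiver.

    Parameters
    ----------
    angle_unit : {"deg", "rad"}
        Unit of the six orientation channels on disk; in-memory angles are
        always degrees.
    axis_signs : tuple of three ints
        Multipliers (+1/-1) applied to (azimuth, elevation, roll) of both
        receivers on read, to map the device's handedness onto the package's
        right-handed ZYX convention.
    """

    angle_unit: str = "deg"
    axis_signs: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.angle_unit not in ("deg", "rad"):
            raise ValueError(f"unknown angle unit {self.angle_unit!r}")
        if any(s not in (-1, 1) for s in self.axis_signs):
            raise ValueError("axis_signs must be +1 or -1")


@dataclass
class RawTrialRecording:
    """One trial's two-receiver 6-DOF time series.

    Angles are ZYX cardan (azimuth-elevation-roll) in degrees; positions in
    the tracker's length unit.  ``direction`` is the instructed outward
    rotation side.
    """

    subject_id: str
    trial_index: int
    direction: str  # "left" | "right"
    sample_rate_hz: float
    time_s: np.ndarray
    head_euler_deg: np.ndarray
    head_pos: np.ndarray
    thorax_euler_deg: np.ndarray
    thorax_pos: np.ndarray
    practice: bool = False
    session: str = "test1"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        for name in ("head_euler_deg", "head_pos", "thorax_euler_deg", "thorax_pos"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    def validate(self) -> None:
        if self.direction not in ("left", "right"):
            raise ValidationError(f"direction must be left/right, got {self.direction!r}")
        if not (1 <= int(self.trial_index) <= 6):
            raise ValidationError(f"trial_index must be in 1..6, got {self.trial_index}")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        n = self.time_s.size
        if n < 2:
            raise ValidationError(f"recording needs >= 2 samples, got {n}")
        for name in ("head_euler_deg", "head_pos", "thorax_euler_deg", "thorax_pos"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValidationError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        nominal = 1.0 / self.sample_rate_hz
        if np.any(np.abs(dt - nominal) > 0.01 * nominal):
            raise ValidationError(
                "sample spacing deviates more than 1% from nominal "
                f"{nominal:.6f} s"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawTrialRecording):
            return NotImplemented
        meta = (
            self.subject_id == other.subject_id
            and self.trial_index == other.trial_index
            and self.direction == other.direction
            and self.practice == other.practice
            and self.session == other.session
            and np.isclose(self.sample_rate_hz, other.sample_rate_hz)
        )
        if not meta:
            return False
        arrays = ("time_s", "head_euler_deg", "head_pos", "thorax_euler_deg", "thorax_pos")
        return all(
            np.array_equal(getattr(self, a), getattr(other, a)) for a in arrays
        )


@dataclass
class SubjectRecord:
    """Subject metadata: group label, age, optional comorbidity flag and the
    self-rated questionnaire block (missing values as NaN)."""

    subject_id: str
    group: str  # "NS" | "CON"
    age_years: float
    low_back_pain: Optional[bool] = None
    questionnaire: dict[str, float] = field(default_factory=dict)
    session: str = "test1"

    def __post_init__(self) -> None:
        if self.group not in ("NS", "CON"):
            raise ValidationError(f"group must be NS or CON, got {self.group!r}")
        if not self.age_years > 0:
            raise ValidationError("age must be positive")
        unknown = set(self.questionnaire) - set(QUESTIONNAIRE_SCHEMA)
        if unknown:
            raise ValidationError(f"unknown questionnaire keys: {sorted(unknown)}")


@dataclass
class CohortDataset:
    """Cross-validated container of subjects and their trial recordings."""

    subjects: list[SubjectRecord]
    recordings: list[RawTrialRecording]
    schema_version: str = "1"
    #: optional ground-truth table attached by the synthetic generator
    latents: Optional[pd.DataFrame] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = {s.subject_id for s in self.subjects}
        counts: dict[tuple[str, str], int] = {}
        for rec in self.recordings:
            if rec.subject_id not in ids:
                raise LinkageError(
                    f"recording references unknown subject {rec.subject_id!r}"
                )
            if not rec.practice:
                key = (rec.subject_id, rec.session)
                counts[key] = counts.get(key, 0) + 1
        for (sid, session), n in counts.items():
            if n > 6:
                raise ValidationError(
                    f"subject {sid!r} session {session!r} has {n} non-practice "
                    "trials (max 6)"
                )

    def subject(self, subject_id: str, session: str = "test1") -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id and s.session == session:
                return s
        raise KeyError((subject_id, session))

    def trials_for(
        self, subject_id: str, session: str = "test1", include_practice: bool = False
    ) -> list[RawTrialRecording]:
        return [
            r
            for r in self.recordings
            if r.subject_id == subject_id
            and r.session == session
            and (include_practice or not r.practice)
        ]


def _apply_dialect(angles: np.ndarray, dialect: DialectConfig) -> np.ndarray:
    out = np.asarray(angles, dtype=float)
    if dialect.angle_unit == "rad":
        out = np.degrees(out)
    return out * np.asarray(dialect.axis_signs, dtype=float)


def read_recording(
    path: str | Path,
    dialect: DialectConfig = DialectConfig(),
    *,
    subject_id: str = "",
    trial_index: int = 1,
    direction: str = "left",
    sample_rate_hz: float = 60.0,
    practice: bool = False,
    session: str = "test1",
) -> RawTrialRecording:
    """Read one trial CSV into a validated :class:`RawTrialRecording`.

    The file must carry a header row naming the 13 channels of
    :data:`CSV_COLUMNS`; metadata not stored in the file (subject, direction,
    ...) is supplied by the caller, normally from the manifest.
    """
    path = Path(path)
    # exact decimal→binary parsing so write/read is the identity
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing channel(s) {missing}")
    return RawTrialRecording(
        subject_id=subject_id,
        trial_index=trial_index,
        direction=direction,
        sample_rate_hz=sample_rate_hz,
        time_s=df["t"].to_numpy(float),
        head_euler_deg=_apply_dialect(df[["haz", "hel", "hro"]].to_numpy(float), dialect),
        head_pos=df[["hx", "hy", "hz"]].to_numpy(float),
        thorax_euler_deg=_apply_dialect(df[["taz", "tel", "tro"]].to_numpy(float), dialect),
        thorax_pos=df[["tx", "ty", "tz"]].to_numpy(float),
        practice=practice,
        session=session,
    )


def write_recording(rec: RawTrialRecording, path: str | Path) -> Path:
    """Write a trial to CSV with full decimal round-trip precision."""
    path = Path(path)
    data = np.column_stack(
        [rec.time_s, rec.head_euler_deg, rec.head_pos, rec.thorax_euler_deg, rec.thorax_pos]
    )
    df = pd.DataFrame(data, columns=list(CSV_COLUMNS))
    # repr-precision floats survive the text round trip bitwise
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def _subjects_from_table(path: Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    subjects = []
    for _, row in df.iterrows():
        q = {
            k: float(row[k])
            for k in QUESTIONNAIRE_SCHEMA
            if k in df.columns and pd.notna(row[k])
        }
        lbp = row.get("low_back_pain")
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age_years=float(row["age_years"]),
                low_back_pain=None if pd.isna(lbp) else bool(lbp),
                questionnaire=q,
                session=str(row.get("session", "test1")),
            )
        )
    return subjects


def load_cohort(manifest: str | Path) -> CohortDataset:
    """Load a cohort from a JSON manifest.

    The manifest lists the subject table and one entry per recording::

        {"subject_table": "subjects.csv",
         "dialect": {"angle_unit": "deg", "axis_signs": [1, 1, 1]},
         "recordings": [{"path": "...", "subject_id": "...", "session": "test1",
                         "trial_index": 1, "direction": "left",
                         "practice": false}, ...]}

    Paths are resolved relative to the manifest's directory.  Practice trials
    are retained but flagged.
    """
    manifest = Path(manifest)
    spec = json.loads(manifest.read_text())
    root = manifest.parent
    dialect_spec = spec.get("dialect", {})
    dialect = DialectConfig(
        angle_unit=dialect_spec.get("angle_unit", "deg"),
        axis_signs=tuple(dialect_spec.get("axis_signs", (1, 1, 1))),
    )
    subjects = _subjects_from_table(root / spec["subject_table"])
    recordings = []
    for entry in spec["recordings"]:
        recordings.append(
            read_recording(
                root / entry["path"],
                dialect,
                subject_id=str(entry["subject_id"]),
                trial_index=int(entry["trial_index"]),
                direction=entry["direction"],
                sample_rate_hz=float(entry.get("sample_rate_hz", 60.0)),
                practice=bool(entry.get("practice", False)),
                session=entry.get("session", "test1"),
            )
        )
    return CohortDataset(
        subjects=subjects,
        recordings=recordings,
        schema_version=str(spec.get("schema_version", "1")),
    )
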