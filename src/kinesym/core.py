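"""Shared data model and on-disk formats.

Recordings are wide delimited text: one row per timestamp, one column per
sensor/modality/axis named ``<sensor>_<gyro|acc|mag>_<x|y|z>`` plus a
``time_s`` column.  Gyroscope units are deg/s, accelerometer units m/s².
Magnetometer columns are accepted and ignored.  Timestamps are seconds from
recording start; task intervals are half-open ``[start_s, end_s)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

GYRO = "gyro"
ACC = "acc"
AXES = ("x", "y", "z")
POSTURES = ("sitting", "standing", "walking")

#: Maximum tolerated relative deviation of any timestamp step from the median.
TIMESTAMP_JITTER_TOL = 0.01


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the format contract."""


# ---------------------------------------------------------------------------
# Sensor layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorLayout:
    """Placement of the 17 inertial units and their segment grouping.

    ``segment_groups`` maps a body-segment name to its member sensors
    (3 per leg, 3 per arm, 4 for the trunk, 1 for the head).
    ``fog_sensors`` are the 7 gait sensors (feet, shanks, thighs, hip);
    the hip is the lowest trunk placement.
    """

    placements: tuple[str, ...]
    segment_groups: dict[str, tuple[str, ...]]
    fog_sensors: tuple[str, ...]
    hand_sensors: tuple[str, ...] = ("hand_l", "hand_r")
    forearm_sensors: tuple[str, ...] = ("forearm_l", "forearm_r")

    def __post_init__(self) -> None:
        if len(self.placements) != 17:
            raise ValueError(f"layout must have 17 sensors, got {len(self.placements)}")
        grouped = [s for g in self.segment_groups.values() for s in g]
        if sorted(grouped) != sorted(self.placements):
            raise ValueError("segment groups do not partition the sensor placements")
        if len(self.fog_sensors) != 7:
            raise ValueError(f"expected 7 gait sensors, got {len(self.fog_sensors)}")
        unknown = set(self.fog_sensors) - set(self.placements)
        if unknown:
            raise ValueError(f"gait sensors not in layout: {sorted(unknown)}")

    @property
    def arm_sensors(self) -> tuple[str, ...]:
        return tuple(s for g in ("arm_l", "arm_r") for s in self.segment_groups[g])

    @property
    def leg_sensors(self) -> tuple[str, ...]:
        return tuple(s for g in ("leg_l", "leg_r") for s in self.segment_groups[g])

    def segment_of(self, sensor: str) -> str:
        for seg, members in self.segment_groups.items():
            if sensor in members:
                return seg
        raise KeyError(sensor)


def default_layout() -> SensorLayout:
    """The 17-sensor full-body suit layout used throughout."""
    groups = {
        "head": ("head",),
        "trunk": ("trunk_upper", "trunk_mid", "trunk_lower", "pelvis"),
        "arm_l": ("upper_arm_l", "forearm_l", "hand_l"),
        "arm_r": ("upper_arm_r", "forearm_r", "hand_r"),
        "leg_l": ("thigh_l", "shank_l", "foot_l"),
        "leg_r": ("thigh_r", "shank_r", "foot_r"),
    }
    placements = tuple(s for g in groups.values() for s in g)
    fog = ("foot_l", "foot_r", "shank_l", "shank_r", "thigh_l", "thigh_r", "pelvis")
    return SensorLayout(placements=placements, segment_groups=groups, fog_sensors=fog)


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Synchronized multi-sensor time series.

    ``gyro`` and ``accel`` map sensor name to an ``(n, 3)`` float array.
    """

    sampling_rate: float
    timestamps: np.ndarray
    gyro: dict[str, np.ndarray]
    accel: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        for name, d in [("gyro", self.gyro), ("acc", self.accel)]:
            for sensor, arr in d.items():
                if arr.shape != (n, 3):
                    raise ValueError(
                        f"{sensor} {name}: shape {arr.shape}, expected ({n}, 3)"
                    )
                if not np.all(np.isfinite(arr)):
                    row = int(np.argwhere(~np.isfinite(arr).all(axis=1))[0, 0])
                    raise FormatError(f"non-finite sample in {sensor} {name} at row {row}")
        if self.sampling_rate < 16.0:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz below the 16 Hz floor "
                "required by the 8 Hz analysis band"
            )

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def sensors(self) -> tuple[str, ...]:
        return tuple(self.gyro)

    def slice(self, start_s: float, end_s: float) -> "Recording":
        """Sub-recording over the half-open interval ``[start_s, end_s)``."""
        i0 = max(0, int(round(start_s * self.sampling_rate)))
        i1 = min(self.n_samples, int(round(end_s * self.sampling_rate)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{start_s}, {end_s})")
        return Recording(
            sampling_rate=self.sampling_rate,
            timestamps=self.timestamps[i0:i1],
            gyro={s: a[i0:i1] for s, a in self.gyro.items()},
            accel={s: a[i0:i1] for s, a in self.accel.items()},
        )


def _columns_for(layout: SensorLayout) -> list[str]:
    cols = ["time_s"]
    for sensor in layout.placements:
        for kind in (GYRO, ACC):
            cols += [f"{sensor}_{kind}_{ax}" for ax in AXES]
    return cols


def read_recording(path, layout: SensorLayout) -> Recording:
    """Read a wide-format recording CSV and validate it against *layout*.

    The sampling rate is inferred from the timestamp column; steps deviating
    more than 1% from the median step are fatal.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = _columns_for(layout)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {', '.join(missing)}")
    if len(df) < 2:
        raise FormatError("recording must contain at least 2 samples")

    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise FormatError("timestamps are not strictly increasing")
    if np.max(np.abs(dt - med)) > TIMESTAMP_JITTER_TOL * med:
        bad = int(np.argmax(np.abs(dt - med))) + 1
        raise FormatError(f"non-uniform timestamps (row {bad} deviates >1% from median step)")

    values = df[required[1:]].to_numpy(dtype=float)
    finite_rows = np.isfinite(values).all(axis=1)
    if not finite_rows.all():
        row = int(np.where(~finite_rows)[0][0])
        raise FormatError(f"non-finite sample at row {row}")

    gyro, accel = {}, {}
    for sensor in layout.placements:
        gyro[sensor] = df[[f"{sensor}_gyro_{ax}" for ax in AXES]].to_numpy(dtype=float)
        accel[sensor] = df[[f"{sensor}_acc_{ax}" for ax in AXES]].to_numpy(dtype=float)
    return Recording(sampling_rate=1.0 / med, timestamps=t, gyro=gyro, accel=accel)


def write_recording(recording: Recording, path) -> None:
    data = {"time_s": recording.timestamps}
    for sensor in recording.sensors:
        for kind, src in ((GYRO, recording.gyro), (ACC, recording.accel)):
            for j, ax in enumerate(AXES):
                data[f"{sensor}_{kind}_{ax}"] = src[sensor][:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Task manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskAnnotation:
    task_id: str
    posture: str
    start_s: float
    end_s: float
    cue_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.posture not in POSTURES:
            raise FormatError(f"unknown posture {self.posture!r} (task {self.task_id})")
        if not self.end_s > self.start_s:
            raise FormatError(f"task {self.task_id}: end_s must exceed start_s")

    @property
    def span_s(self) -> float:
        return self.end_s - self.start_s


def read_task_manifest(path) -> list[TaskAnnotation]:
    """Read a task manifest CSV, returning annotations sorted by start time.

    Overlapping intervals are kept but trigger a warning.  Extra columns
    are ignored so the same file may carry pipeline bookkeeping fields.
    """
    df = pd.read_csv(path)
    if df.empty:
        return []
    required = ["task_id", "posture", "start_s", "end_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {', '.join(missing)}")
    annotations = []
    for _, row in df.iterrows():
        annotations.append(
            TaskAnnotation(
                task_id=str(row["task_id"]),
                posture=str(row["posture"]),
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
                cue_time_s=float(row.get("cue_time_s", row["start_s"])),
            )
        )
    annotations.sort(key=lambda a: a.start_s)
    for prev, cur in zip(annotations, annotations[1:]):
        if cur.start_s < prev.end_s:
            warnings.warn(
                f"tasks {prev.task_id} and {cur.task_id} overlap in time", stacklevel=2
            )
    return annotations


# ---------------------------------------------------------------------------
# Symptom table
# ---------------------------------------------------------------------------

@dataclass
class SymptomScores:
    """Per participant × task symptom levels (the derived predictors)."""

    participant_id: str
    task_id: str
    tremor_level: float = np.nan
    lid_score: float = np.nan
    fog_pct: float = np.nan
    bradykinesia_level: float = np.nan


SYMPTOM_COLUMNS = [f.name for f in fields(SymptomScores)]


def write_symptom_table(scores: list[SymptomScores], path) -> None:
    """Write symptom scores as CSV with a stable column order.

    An empty list yields a header-only file.  Floats are written at full
    round-trip precision.
    """
    df = pd.DataFrame(
        [{c: getattr(s, c) for c in SYMPTOM_COLUMNS} for s in scores],
        columns=SYMPTOM_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")  # exact float round-trip


def read_symptom_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SYMPTOM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"symptom table missing columns: {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

#: Columns of the participant × task cohort table consumed by the statistics
#: stage.  ``success`` is derived downstream and therefore optional on read.
COHORT_COLUMNS = [
    "participant_id", "group", "task_id", "age", "mmse",
    "rigidity", "postural_instability",
    "lid_level", "tremor_level", "bradykinesia_level", "fog_pct",
    "time_s", "error_count",
]


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns: {', '.join(missing)}")
    bad_group = set(df["group"].unique()) - {"control", "patient"}
    if bad_group:
        raise FormatError(f"unknown group labels: {sorted(bad_group)}")
    if (df["error_count"] < 0).any():
        raise FormatError("error_count must be >= 0")
    mmse = df["mmse"].dropna()
    if ((mmse < 0) | (mmse > 30)).any():
        raise FormatError("mmse must lie in [0, 30]")
    return df


def read_cohort_table(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, float_precision="round_trip"))
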