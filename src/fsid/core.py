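"""Data model and on-disk formats for two-IMU shoulder-task recordings.

A recording couples two sensors (arm and wrist), each carrying a tri-axial
accelerometer (units of g) and a tri-axial gyroscope (units of deg/s) sampled
at a common rate (128 Hz by default).  Each shoulder task carries a
ground-truth segmentation into one complete-task interval and three ordered
subtask intervals (lift / sustain / return).

Interval convention: 0-based, half-open ``[start, end)`` sample indices.

On-disk layout per task: a CSV with columns
``t,arm_ax,...,arm_gz,wrist_ax,...,wrist_gz`` (t in seconds) plus a JSON
sidecar with the task label, sampling rate and annotation indices.  A cohort
is a manifest JSON listing subjects, group labels and per-task file paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Task",
    "Group",
    "Placement",
    "ValidationError",
    "TriaxialSignal",
    "SensorRecording",
    "SegmentAnnotation",
    "TaskRecording",
    "Subject",
    "Cohort",
    "extract_segment",
    "write_recording",
    "read_recording",
    "write_cohort",
    "read_cohort",
]

CSV_COLUMNS = [
    "t",
    "arm_ax", "arm_ay", "arm_az", "arm_gx", "arm_gy", "arm_gz",
    "wrist_ax", "wrist_ay", "wrist_az", "wrist_gx", "wrist_gy", "wrist_gz",
]


class Task(str, Enum):
    """The five SPADI-derived shoulder tasks."""

    WH = "WH"      # washing hair
    WUB = "WUB"    # washing upper back
    WLB = "WLB"    # washing lower back
    POH = "POH"    # placing an object on a high shelf
    ROP = "ROP"    # removing an object from the back pocket


class Group(str, Enum):
    FS = "FS"
    HEALTHY = "healthy"


class Placement(str, Enum):
    ARM = "arm"
    WRIST = "wrist"


class ValidationError(ValueError):
    """Raised when an on-disk file or in-memory object violates an invariant."""


@dataclass(frozen=True)
class TriaxialSignal:
    """Three equal-length axis series sampled at ``fs`` Hz.

    ``xyz`` has shape (n, 3).  Units are g for acceleration and deg/s for
    angular velocity; the container itself is unit-agnostic.
    """

    xyz: np.ndarray
    fs: float = 128.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.xyz, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValidationError(f"xyz must have shape (n, 3), got {arr.shape}")
        if arr.shape[0] < 2:
            raise ValidationError("signal length must be >= 2 samples")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "xyz", arr)

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def slice(self, start: int, end: int) -> "TriaxialSignal":
        return TriaxialSignal(self.xyz[start:end], self.fs)


@dataclass(frozen=True)
class SensorRecording:
    """One IMU: synchronized accelerometer (g) and gyroscope (deg/s)."""

    accel: TriaxialSignal
    gyro: TriaxialSignal
    placement: Placement

    def __post_init__(self) -> None:
        if len(self.accel) != len(self.gyro):
            raise ValidationError(
                f"accel ({len(self.accel)}) and gyro ({len(self.gyro)}) lengths differ"
            )
        if self.accel.fs != self.gyro.fs:
            raise ValidationError("accel and gyro sampling rates differ")

    def __len__(self) -> int:
        return len(self.accel)

    @property
    def fs(self) -> float:
        return self.accel.fs


@dataclass(frozen=True)
class SegmentAnnotation:
    """Half-open [start, end) sample intervals: one complete task, three subtasks.

    Subtasks are ordered, non-overlapping and contained in the complete
    interval; every interval spans at least 2 samples.
    """

    complete: tuple[int, int]
    subtasks: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        intervals = [self.complete, *self.subtasks]
        if len(self.subtasks) != 3:
            raise ValidationError("exactly three subtask intervals required")
        for name, (s, e) in zip(["complete", "subtask1", "subtask2", "subtask3"], intervals):
            if not (0 <= s < e):
                raise ValidationError(f"{name} interval ({s}, {e}) is not a valid [start, end)")
            if e - s < 2:
                raise ValidationError(f"{name} interval shorter than 2 samples")
        cs, ce = self.complete
        prev_end = cs
        for i, (s, e) in enumerate(self.subtasks, start=1):
            if s < prev_end:
                raise ValidationError(f"subtask{i} overlaps or precedes its predecessor")
            if not (cs <= s and e <= ce):
                raise ValidationError(f"subtask{i} not contained in the complete interval")
            prev_end = e

    def segments(self) -> Iterator[tuple[str, tuple[int, int]]]:
        yield "complete", self.complete
        for i, iv in enumerate(self.subtasks, start=1):
            yield f"subtask{i}", iv

    def to_dict(self) -> dict:
        return {
            "complete": list(self.complete),
            **{f"subtask{i}": list(iv) for i, iv in enumerate(self.subtasks, start=1)},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SegmentAnnotation":
        try:
            complete = tuple(int(v) for v in d["complete"])
            subs = tuple(tuple(int(v) for v in d[f"subtask{i}"]) for i in (1, 2, 3))
        except KeyError as exc:
            raise ValidationError(f"annotation missing segment {exc}") from exc
        return cls(complete, subs)  # type: ignore[arg-type]


@dataclass(frozen=True)
class TaskRecording:
    """Arm + wrist sensor streams of one shoulder task with its annotation."""

    task: Task
    arm: SensorRecording
    wrist: SensorRecording
    annotation: SegmentAnnotation
    duration_s: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.arm) != len(self.wrist):
            raise ValidationError("arm and wrist recordings have different lengths")
        if self.arm.fs != self.wrist.fs:
            raise ValidationError("arm and wrist sampling rates differ")
        cs, ce = self.annotation.complete
        if ce > len(self.arm):
            raise ValidationError("annotation out of bounds: complete interval exceeds signal length")
        implied = (ce - cs) / self.fs
        if self.duration_s is None:
            object.__setattr__(self, "duration_s", implied)
        elif abs(self.duration_s - implied) > 1e-9:
            raise ValidationError(
                f"duration_s {self.duration_s} inconsistent with complete interval ({implied})"
            )

    def __len__(self) -> int:
        return len(self.arm)

    @property
    def fs(self) -> float:
        return self.arm.fs

    def sensor(self, placement: Placement | str) -> SensorRecording:
        placement = Placement(placement)
        return self.arm if placement is Placement.ARM else self.wrist


@dataclass(frozen=True)
class Subject:
    """One sampled shoulder: a group label and one recording per task."""

    subject_id: str
    group: Group
    tasks: Mapping[Task, TaskRecording]

    def __post_init__(self) -> None:
        labels = set(self.tasks.keys())
        if labels != set(Task):
            missing = sorted(t.value for t in set(Task) - labels)
            raise ValidationError(f"subject {self.subject_id} missing tasks: {missing}")


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[Subject, ...]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject_ids are not unique")
        object.__setattr__(self, "subjects", tuple(self.subjects))

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)


def extract_segment(rec: SensorRecording, interval: Sequence[int]) -> SensorRecording:
    """Slice a sensor recording over half-open sample indices ``[start, end)``."""
    start, end = int(interval[0]), int(interval[1])
    if not (0 <= start < end <= len(rec)):
        raise ValidationError(
            f"interval ({start}, {end}) out of range for recording of length {len(rec)}"
        )
    return SensorRecording(rec.accel.slice(start, end), rec.gyro.slice(start, end), rec.placement)


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(rec: TaskRecording, path: str | Path) -> None:
    """Write one task recording as ``path`` (CSV) plus a JSON sidecar."""
    path = Path(path)
    n = len(rec)
    t = np.arange(n) / rec.fs
    data = np.column_stack([t, rec.arm.accel.xyz, rec.arm.gyro.xyz,
                            rec.wrist.accel.xyz, rec.wrist.gyro.xyz])
    df = pd.DataFrame(data, columns=CSV_COLUMNS)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "task": rec.task.value,
        "fs": rec.fs,
        "annotation": rec.annotation.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> TaskRecording:
    """Read a task recording written by :func:`write_recording`.

    The sampling rate is inferred from the spacing of the ``t`` column and
    cross-checked against the sidecar.  All type invariants are enforced;
    malformed files raise :class:`ValidationError` naming the offending field.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"CSV missing columns: {missing}")
    if len(df) < 2:
        raise ValidationError("CSV has fewer than 2 data rows")
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError("t column is not strictly increasing")
    fs = 1.0 / float(np.median(dt))

    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise ValidationError(f"annotation sidecar not found: {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    if "fs" in sidecar and abs(sidecar["fs"] - fs) / sidecar["fs"] > 0.01:
        raise ValidationError(
            f"fs from sidecar ({sidecar['fs']}) disagrees with t-column spacing ({fs:.3f})"
        )
    fs = float(sidecar.get("fs", fs))
    annotation = SegmentAnnotation.from_dict(sidecar["annotation"])
    if annotation.complete[1] > len(df):
        raise ValidationError("annotation out of bounds: interval exceeds signal length")

    def sensor(prefix: str, placement: Placement) -> SensorRecording:
        acc = df[[f"{prefix}_ax", f"{prefix}_ay", f"{prefix}_az"]].to_numpy(dtype=float)
        gyr = df[[f"{prefix}_gx", f"{prefix}_gy", f"{prefix}_gz"]].to_numpy(dtype=float)
        return SensorRecording(TriaxialSignal(acc, fs), TriaxialSignal(gyr, fs), placement)

    return TaskRecording(
        task=Task(sidecar["task"]),
        arm=sensor("arm", Placement.ARM),
        wrist=sensor("wrist", Placement.WRIST),
        annotation=annotation,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write every recording of a cohort plus a manifest JSON; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": []}
    for subj in cohort:
        entry = {"subject_id": subj.subject_id, "group": subj.group.value, "tasks": {}}
        for task in Task:
            rel = f"{subj.subject_id}/{task.value}.csv"
            write_recording(subj.tasks[task], out_dir / rel)
            entry["tasks"][task.value] = rel
        manifest["subjects"].append(entry)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_cohort(manifest_path: str | Path) -> Cohort:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    subjects = []
    for entry in manifest["subjects"]:
        tasks = {
            Task(name): read_recording(root / rel)
            for name, rel in entry["tasks"].items()
        }
        subjects.append(Subject(entry["subject_id"], Group(entry["group"]), tasks))
    return Cohort(tuple(subjects))
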