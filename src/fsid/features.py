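"""Time-domain statistical and kinematic feature extraction for shoulder-task IMU signals.

Channel derivation
    From each tri-axial signal, seven channels: the three axes, the three
    plane magnitudes (horizontal = sqrt(y^2+z^2), coronal = sqrt(x^2+z^2),
    sagittal = sqrt(x^2+y^2)) and the Euclidean norm.

Statistical bank
    Eight statistics (mean, SD, variance, max, min, range, kurtosis,
    skewness) over each of the 14 channels of one IMU = 112 features per IMU
    per segment.  With two IMUs and four segments (complete + three subtasks)
    a task yields 896 statistical features.  SD/variance are population
    moments; kurtosis is excess kurtosis; skewness and kurtosis of a constant
    channel are defined as 0.

Kinematic bank
    Thirteen features per segment: number of mean-crossing points (NMCP) and
    number of prominent peaks (NP) of the acceleration norm, spectral arc
    length (SPARC) of the angular-velocity norm, log dimensionless jerk
    (LDLJ) of the acceleration norm, range of angular velocity (RAV), power
    index (PI) — each for arm and wrist — plus the segment duration.  Four
    segments give 52 kinematic features, for a task total of 948.

SPARC is the negated arc length of the normalized magnitude spectrum of the
angular-velocity norm below an adaptive cutoff: fragmented movement spreads
power to higher frequencies, lengthening the arc, so smoother movement gives
a SPARC closer to 0 (always negative).  LDLJ is
``-ln( T^3 / v_peak^2 * \\int (d^2 v/dt^2)^2 dt )`` computed on the
acceleration norm ``v`` over segment duration ``T``; this normalization makes
it invariant to amplitude and (in the continuum limit) duration rescaling,
with smoother movement giving larger (less negative) values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import find_peaks

from .core import (
    Cohort,
    Placement,
    SensorRecording,
    Task,
    TaskRecording,
    TriaxialSignal,
    extract_segment,
)

__all__ = [
    "ChannelSet",
    "FeatureVector",
    "FeatureSchema",
    "DegenerateSignalError",
    "derive_channels",
    "stat_features",
    "nmcp",
    "count_peaks",
    "sparc",
    "ldlj",
    "rav",
    "power_index",
    "kinematic_features",
    "task_feature_vector",
    "feature_schema",
    "extract_cohort_features",
    "STAT_NAMES",
    "ACCEL_CHANNELS",
    "GYRO_CHANNELS",
    "KINEMATIC_NAMES",
    "SEGMENT_NAMES",
]

SEGMENT_NAMES = ("complete", "subtask1", "subtask2", "subtask3")
STAT_NAMES = ("mean", "std", "var", "max", "min", "range", "kurtosis", "skewness")
ACCEL_CHANNELS = ("ax", "ay", "az", "ahori", "acoro", "asagi", "anorm")
GYRO_CHANNELS = ("gx", "gy", "gz", "ghori", "gcoro", "gsagi", "gnorm")
KINEMATIC_NAMES = (
    "nmcp_arm", "nmcp_wrist",
    "np_arm", "np_wrist",
    "sparc_arm", "sparc_wrist",
    "ldlj_arm", "ldlj_wrist",
    "rav_arm", "rav_wrist",
    "pi_arm", "pi_wrist",
    "duration",
)

N_STAT_PER_IMU = 112
N_STAT_TOTAL = 896
N_KIN_PER_SEGMENT = 13
N_KIN_TOTAL = 52
N_FEATURES_TOTAL = 948

SPARC_AMP_THRESHOLD = 0.05
SPARC_MAX_CUTOFF_HZ = 10.0
SPARC_PADLEVEL = 4
NP_PROMINENCE_FRAC = 0.05


class DegenerateSignalError(ValueError):
    """Raised when a smoothness metric is undefined (flat or all-zero input)."""


@dataclass(frozen=True)
class ChannelSet:
    """Seven derived acceleration channels and seven angular-velocity channels."""

    A: np.ndarray  # shape (n, 7): ax, ay, az, ahori, acoro, asagi, anorm
    W: np.ndarray  # shape (n, 7): gx, gy, gz, ghori, gcoro, gsagi, gnorm
    fs: float

    @property
    def anorm(self) -> np.ndarray:
        return self.A[:, 6]

    @property
    def gnorm(self) -> np.ndarray:
        return self.W[:, 6]


def _derive_one(xyz: np.ndarray) -> np.ndarray:
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    hori = np.sqrt(y**2 + z**2)
    coro = np.sqrt(x**2 + z**2)
    sagi = np.sqrt(x**2 + y**2)
    norm = np.sqrt(x**2 + y**2 + z**2)
    return np.column_stack([x, y, z, hori, coro, sagi, norm])


def derive_channels(accel: TriaxialSignal, gyro: TriaxialSignal) -> ChannelSet:
    """Expand one IMU's two tri-axial signals into the 14 derived channels."""
    if len(accel) != len(gyro):
        raise ValueError("accel and gyro lengths differ")
    return ChannelSet(A=_derive_one(accel.xyz), W=_derive_one(gyro.xyz), fs=accel.fs)


def _stats_of(col: np.ndarray) -> dict[str, float]:
    sd = float(np.std(col))  # population
    vals = {
        "mean": float(np.mean(col)),
        "std": sd,
        "var": float(np.var(col)),
        "max": float(np.max(col)),
        "min": float(np.min(col)),
        "range": float(np.max(col) - np.min(col)),
    }
    # a channel that is constant up to float round-off has no defined shape moments
    if sd <= 1e-12 * max(1.0, abs(vals["mean"])):
        vals["kurtosis"] = 0.0
        vals["skewness"] = 0.0
    else:
        vals["kurtosis"] = float(sps.kurtosis(col, fisher=True, bias=True))
        vals["skewness"] = float(sps.skew(col, bias=True))
    return vals


def stat_features(ch: ChannelSet) -> np.ndarray:
    """The 112 statistical features of one IMU segment.

    Order is statistic-major: for each of the eight statistics, the seven
    acceleration channels then the seven angular-velocity channels.
    """
    per_channel = [_stats_of(ch.A[:, j]) for j in range(7)]
    per_channel += [_stats_of(ch.W[:, j]) for j in range(7)]
    out = np.empty(N_STAT_PER_IMU)
    k = 0
    for stat in STAT_NAMES:
        for d in per_channel:
            out[k] = d[stat]
            k += 1
    return out


def stat_feature_names(sensor: str) -> list[str]:
    names = []
    for stat in STAT_NAMES:
        for ch in ACCEL_CHANNELS + GYRO_CHANNELS:
            names.append(f"{sensor}.{stat}_{ch}")
    return names


def nmcp(signal: Sequence[float]) -> int:
    """Number of mean-crossing points: strict sign changes of (signal - mean).

    Samples exactly equal to the mean do not count as crossings.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("signal must have length >= 2")
    s = x - x.mean()
    return int(np.count_nonzero(s[:-1] * s[1:] < 0))


def count_peaks(signal: Sequence[float], prominence_frac: float = NP_PROMINENCE_FRAC) -> int:
    """Number of local maxima with prominence >= prominence_frac * (max - min)."""
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("signal must have length >= 3")
    if not 0 < prominence_frac < 1:
        raise ValueError("prominence_frac must lie in (0, 1)")
    span = float(x.max() - x.min())
    if span == 0.0:
        return 0
    peaks, _ = find_peaks(x, prominence=prominence_frac * span)
    return int(peaks.size)


def _magnitude_spectrum(x: np.ndarray, fs: float, padlevel: int) -> tuple[np.ndarray, np.ndarray]:
    nfft = 2 ** (int(np.ceil(np.log2(x.size))) + padlevel)
    freqs = np.arange(nfft // 2 + 1) * fs / nfft
    mag = np.abs(np.fft.rfft(x, nfft))
    return freqs, mag


def sparc(
    omega_norm: Sequence[float],
    fs: float,
    amp_threshold: float = SPARC_AMP_THRESHOLD,
    max_cutoff: float = SPARC_MAX_CUTOFF_HZ,
    padlevel: int = SPARC_PADLEVEL,
) -> float:
    """Spectral arc length of a movement-speed profile (more negative = less smooth).

    The magnitude spectrum is computed with zero-padding to at least
    ``2**padlevel`` times the next power of two, normalized by its DC value,
    and truncated at the highest frequency <= ``max_cutoff`` where it still
    reaches ``amp_threshold``.  The returned value is the negated arc length
    of the normalized spectrum over [0, cutoff], with frequency scaled by the
    cutoff so the measure is resolution- and cutoff-normalized.
    """
    x = np.asarray(omega_norm, dtype=float)
    if x.size < 4:
        raise ValueError("signal must have length >= 4")
    freqs, mag = _magnitude_spectrum(x, fs, padlevel)
    if mag[0] == 0.0:
        raise DegenerateSignalError("degenerate spectrum: zero-mean or all-zero signal")
    vhat = mag / mag[0]

    band = freqs <= max_cutoff
    f_band, v_band = freqs[band], vhat[band]
    above = np.nonzero(v_band >= amp_threshold)[0]
    cutoff = f_band[above[-1]]
    if cutoff == 0.0:
        raise DegenerateSignalError("degenerate spectrum: no content above threshold")
    sel = f_band <= cutoff
    f_sel, v_sel = f_band[sel], v_band[sel]

    dv = np.gradient(v_sel, f_sel)
    integrand = np.sqrt((1.0 / cutoff) ** 2 + dv**2)
    return -float(np.trapezoid(integrand, f_sel))


def ldlj(alpha_norm: Sequence[float], fs: float) -> float:
    """Log dimensionless jerk of an acceleration-magnitude profile.

    ``-ln( T^3 / v_peak^2 * \\int (v'')^2 dt )`` with the second derivative by
    central differences (4th-order stencil in the interior, 2nd-order at the
    edges, so the value is stable under time rescaling at 128 Hz) and
    trapezoidal integration over the segment.
    """
    v = np.asarray(alpha_norm, dtype=float)
    if v.size < 5:
        raise ValueError("signal must have length >= 5")
    vpeak = float(np.max(np.abs(v)))
    if vpeak == 0.0:
        raise DegenerateSignalError("degenerate signal: zero peak amplitude")
    dt = 1.0 / fs
    d2v = np.empty_like(v)
    d2v[2:-2] = (-v[4:] + 16 * v[3:-1] - 30 * v[2:-2] + 16 * v[1:-3] - v[:-4]) / (12 * dt**2)
    d2v[1] = (v[2] - 2 * v[1] + v[0]) / dt**2
    d2v[-2] = (v[-1] - 2 * v[-2] + v[-3]) / dt**2
    d2v[0], d2v[-1] = d2v[1], d2v[-2]
    integral = float(np.trapezoid(d2v**2, dx=dt))
    if integral <= 0.0:
        raise DegenerateSignalError("degenerate signal: zero jerk")
    duration = (v.size - 1) * dt
    return -float(np.log(duration**3 / vpeak**2 * integral))


def rav(gyro: TriaxialSignal) -> float:
    """Range of angular velocity: per-axis (max - min), averaged over the three axes."""
    ranges = gyro.xyz.max(axis=0) - gyro.xyz.min(axis=0)
    return float(ranges.mean())


def power_index(accel: TriaxialSignal, gyro: TriaxialSignal) -> float:
    """Power index: sum over paired axes of accel range times gyro range."""
    if len(accel) != len(gyro):
        raise ValueError("accel and gyro lengths differ")
    a_rng = accel.xyz.max(axis=0) - accel.xyz.min(axis=0)
    g_rng = gyro.xyz.max(axis=0) - gyro.xyz.min(axis=0)
    return float(np.dot(a_rng, g_rng))


def kinematic_features(
    arm: SensorRecording, wrist: SensorRecording, duration_s: float
) -> np.ndarray:
    """The 13 kinematic features of one segment (arm/wrist pairs + duration)."""
    arm_ch = derive_channels(arm.accel, arm.gyro)
    wrist_ch = derive_channels(wrist.accel, wrist.gyro)
    return np.array([
        nmcp(arm_ch.anorm),
        nmcp(wrist_ch.anorm),
        count_peaks(arm_ch.anorm),
        count_peaks(wrist_ch.anorm),
        sparc(arm_ch.gnorm, arm.fs),
        sparc(wrist_ch.gnorm, wrist.fs),
        ldlj(arm_ch.anorm, arm.fs),
        ldlj(wrist_ch.anorm, wrist.fs),
        rav(arm.gyro),
        rav(wrist.gyro),
        power_index(arm.accel, arm.gyro),
        power_index(wrist.accel, wrist.gyro),
        duration_s,
    ])


@dataclass(frozen=True)
class FeatureSchema:
    """Canonical feature ordering and group/placement index masks.

    ``masks`` maps (block, placement) with block in {"statistical",
    "kinematic"} and placement in {"arm", "wrist"} to sorted index arrays.
    The per-segment duration is attributed to the wrist (it is defined by the
    wrist returning to its initial position).
    """

    names: tuple[str, ...]
    masks: dict[tuple[str, str], np.ndarray]

    def select(self, feature_set: str = "all", placement: str = "both") -> np.ndarray:
        """Sorted column indices for a (feature set, sensor placement) choice."""
        blocks = {
            "all": ("statistical", "kinematic"),
            "statistical": ("statistical",),
            "kinematic": ("kinematic",),
        }[feature_set]
        placements = {"both": ("arm", "wrist"), "arm": ("arm",), "wrist": ("wrist",)}[placement]
        idx = np.concatenate([self.masks[(b, p)] for b in blocks for p in placements])
        return np.sort(idx)

    def __len__(self) -> int:
        return len(self.names)


def feature_schema() -> FeatureSchema:
    """Build the canonical 948-feature schema (segment-major, arm before wrist)."""
    names: list[str] = []
    masks: dict[tuple[str, str], list[int]] = {
        ("statistical", "arm"): [],
        ("statistical", "wrist"): [],
        ("kinematic", "arm"): [],
        ("kinematic", "wrist"): [],
    }
    for seg in SEGMENT_NAMES:
        for sensor in ("arm", "wrist"):
            for n in stat_feature_names(sensor):
                masks[("statistical", sensor)].append(len(names))
                names.append(f"{seg}.{n}")
        for kname in KINEMATIC_NAMES:
            sensor = "wrist" if (kname.endswith("_wrist") or kname == "duration") else "arm"
            masks[("kinematic", sensor)].append(len(names))
            names.append(f"{seg}.kin.{kname}")
    return FeatureSchema(
        names=tuple(names),
        masks={k: np.asarray(v, dtype=int) for k, v in masks.items()},
    )


_SCHEMA = feature_schema()


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, named feature values of one task instance."""

    values: np.ndarray
    schema: FeatureSchema = _SCHEMA

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.schema),):
            raise ValueError(
                f"expected {len(self.schema)} features, got {self.values.shape}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return self.schema.names


def task_feature_vector(rec: TaskRecording, schema: FeatureSchema = _SCHEMA) -> FeatureVector:
    """Extract the full 948-feature vector of one task recording.

    Per segment (complete + three subtasks): 112 statistical features for the
    arm IMU, 112 for the wrist IMU, then the 13 kinematic features.  Segment
    duration is the segment's sample span divided by the sampling rate.
    """
    values: list[np.ndarray] = []
    for _, interval in rec.annotation.segments():
        arm_seg = extract_segment(rec.arm, interval)
        wrist_seg = extract_segment(rec.wrist, interval)
        values.append(stat_features(derive_channels(arm_seg.accel, arm_seg.gyro)))
        values.append(stat_features(derive_channels(wrist_seg.accel, wrist_seg.gyro)))
        seg_duration = (interval[1] - interval[0]) / rec.fs
        values.append(kinematic_features(arm_seg, wrist_seg, seg_duration))
    return FeatureVector(values=np.concatenate(values), schema=schema)


def extract_cohort_features(cohort: Cohort, schema: FeatureSchema = _SCHEMA) -> pd.DataFrame:
    """One row per task instance: subject_id, group, task + the 948 named features."""
    rows = []
    for subj in cohort:
        for task in Task:
            fv = task_feature_vector(subj.tasks[task], schema)
            rows.append((subj.subject_id, subj.group.value, task.value, fv.values))
    meta = pd.DataFrame(
        [(sid, grp, tsk) for sid, grp, tsk, _ in rows],
        columns=["subject_id", "group", "task"],
    )
    feats = pd.DataFrame(
        np.vstack([v for _, _, _, v in rows]), columns=list(schema.names)
    )
    return pd.concat([meta, feats], axis=1)
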