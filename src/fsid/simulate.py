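"""Synthetic two-IMU shoulder-task cohorts with healthy vs frozen-shoulder signatures.

Each task is modelled as a single rotational degree of freedom of the arm
(elevation for overhead tasks, an internal-rotation path for behind-the-back
tasks).  A task has three phases — lift, sustain, return — preceded and
followed by short rest padding.  The lift is a superposition of
``n_submovements`` time-shifted minimum-jerk strokes: one stroke gives the
smooth bell-shaped velocity profile of an unimpaired reach, several
overlapping strokes give the fragmented, multi-peaked profile characteristic
of painful, guarded movement.  Frozen-shoulder (FS) subjects additionally show
reduced amplitude, prolonged duration and higher sensor noise.

The gyroscope reports the analytic derivative of the joint angle distributed
over a task-specific rotation axis.  The accelerometer reports gravity
projected through the instantaneous limb angle plus tangential and centripetal
movement components at the sensor radius, so the norm is ~1 g at rest and
gravity is never removed.  The wrist sensor sits further from the joint than
the arm sensor, so its movement-induced amplitudes are scaled up by a fixed
lever factor.

All randomness flows from a single master seed via ``numpy`` SeedSequence
spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .core import (
    Cohort,
    Group,
    Placement,
    SegmentAnnotation,
    SensorRecording,
    Subject,
    Task,
    TaskRecording,
    TriaxialSignal,
)

__all__ = [
    "MovementProfile",
    "TaskGeometry",
    "TASK_GEOMETRY",
    "minimum_jerk",
    "minimum_jerk_velocity",
    "default_profiles",
    "generate_task",
    "generate_subject",
    "generate_cohort",
]

FS_HZ = 128.0
GRAVITY_M_S2 = 9.81
#: Wrist sensor sits further from the shoulder than the arm sensor; movement
#: amplitudes (angular rate and linear acceleration) scale with this lever.
WRIST_LEVER = 1.6
ARM_RADIUS_M = 0.15
HOLD_OSC_HZ = 2.0       # scrubbing/holding oscillation during the sustain phase
REST_PAD_S = 0.5        # quiet standing before/after the complete task


@dataclass(frozen=True)
class MovementProfile:
    """Per-group movement signature.

    amplitude_scale
        Multiplier on the task's peak angular excursion (FS < 1: limited ROM).
    duration_scale
        Multiplier on all phase durations (FS > 1: slower performance).
    n_submovements
        Number of overlapping minimum-jerk strokes composing the lift and
        return phases; 1 = smooth, >1 = fragmented.
    tremor_sd
        SD of additive Gaussian accelerometer noise, in g.
    gyro_noise_sd
        SD of additive Gaussian gyroscope noise, in deg/s.
    hold_oscillation_amp
        Relative amplitude of the sustain-phase oscillation (scrubbing).
    """

    amplitude_scale: float = 1.0
    duration_scale: float = 1.0
    n_submovements: int = 1
    tremor_sd: float = 0.02
    gyro_noise_sd: float = 1.0
    hold_oscillation_amp: float = 0.1

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0 or self.duration_scale <= 0:
            raise ValueError("amplitude_scale and duration_scale must be > 0")
        if self.n_submovements < 1:
            raise ValueError("n_submovements must be >= 1")
        if self.tremor_sd < 0 or self.gyro_noise_sd < 0 or self.hold_oscillation_amp < 0:
            raise ValueError("noise and oscillation amplitudes must be >= 0")


@dataclass(frozen=True)
class TaskGeometry:
    """Baseline kinematics of one shoulder task (healthy, scale 1)."""

    excursion_deg: float              # peak angular excursion from rest
    phase_s: tuple[float, float, float]   # lift, sustain, return durations
    axis: tuple[float, float, float]      # unit rotation axis in the sensor frame


def _unit(v: tuple[float, float, float]) -> tuple[float, float, float]:
    n = float(np.linalg.norm(v))
    return (v[0] / n, v[1] / n, v[2] / n)


TASK_GEOMETRY: Mapping[Task, TaskGeometry] = {
    Task.WH: TaskGeometry(150.0, (1.5, 2.0, 1.5), _unit((0.15, 0.10, 0.98))),
    Task.WUB: TaskGeometry(120.0, (1.4, 2.2, 1.4), _unit((0.30, 0.20, 0.93))),
    Task.WLB: TaskGeometry(70.0, (1.6, 2.5, 1.6), _unit((0.60, 0.35, 0.72))),
    Task.POH: TaskGeometry(160.0, (1.5, 1.5, 1.5), _unit((0.10, 0.15, 0.98))),
    Task.ROP: TaskGeometry(80.0, (1.3, 1.8, 1.3), _unit((0.55, 0.45, 0.70))),
}


def default_profiles() -> tuple[MovementProfile, MovementProfile]:
    """Return the (healthy, FS) movement profiles used throughout.

    Healthy: full amplitude, nominal pace, a single smooth stroke, low noise.
    FS: 60% amplitude, 1.5x duration, three overlapping sub-movements,
    elevated tremor, and weaker sustain-phase scrubbing.
    """
    healthy = MovementProfile(
        amplitude_scale=1.0, duration_scale=1.0, n_submovements=1,
        tremor_sd=0.02, gyro_noise_sd=1.0, hold_oscillation_amp=0.1,
    )
    fs = MovementProfile(
        amplitude_scale=0.6, duration_scale=1.5, n_submovements=3,
        tremor_sd=0.05, gyro_noise_sd=2.0, hold_oscillation_amp=0.05,
    )
    return healthy, fs


def minimum_jerk(t: np.ndarray | float, amplitude: float = 1.0) -> np.ndarray | float:
    """Minimum-jerk position profile on normalized time ``t`` in [0, 1].

    Returns ``amplitude * (10 t^3 - 15 t^4 + 6 t^5)``: the smoothest point-to-
    point trajectory, with zero velocity and acceleration at both endpoints.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > 1):
        raise ValueError("normalized time must lie in [0, 1]")
    out = amplitude * (10 * t_arr**3 - 15 * t_arr**4 + 6 * t_arr**5)
    return out if np.ndim(t) else float(out)


def minimum_jerk_velocity(t: np.ndarray | float, amplitude: float = 1.0) -> np.ndarray | float:
    """d/dt of :func:`minimum_jerk` on normalized time (multiply by 1/T for real time)."""
    t_arr = np.asarray(t, dtype=float)
    out = amplitude * (30 * t_arr**2 - 60 * t_arr**3 + 30 * t_arr**4)
    return out if np.ndim(t) else float(out)


def _submovement_plan(
    rng: np.random.Generator, n_sub: int, phase_len: float, total_amp: float
) -> list[tuple[float, float, float]]:
    """Decompose one transport phase into (onset, duration, amplitude) strokes.

    With ``n_sub == 1`` the single stroke deterministically spans the whole
    phase.  Otherwise onsets are staggered over the first 60% of the phase,
    durations cover 45-75% of it, and amplitudes are a random positive
    partition of the total excursion.
    """
    if n_sub == 1:
        return [(0.0, phase_len, total_amp)]
    onsets = np.sort(rng.uniform(0.0, 0.6 * phase_len, size=n_sub))
    onsets[0] = 0.0
    durations = rng.uniform(0.45, 0.75, size=n_sub) * phase_len
    durations = np.minimum(durations, phase_len - onsets)
    weights = rng.dirichlet(np.full(n_sub, 3.0))
    return [(float(o), float(d), float(w) * total_amp) for o, d, w in zip(onsets, durations, weights)]


def _phase_angle(
    t: np.ndarray, plan: list[tuple[float, float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Angle (deg) and analytic angular velocity (deg/s) of a stroke superposition."""
    theta = np.zeros_like(t)
    omega = np.zeros_like(t)
    for onset, dur, amp in plan:
        tau = np.clip((t - onset) / dur, 0.0, 1.0)
        theta += minimum_jerk(tau, amp)
        active = (t >= onset) & (t <= onset + dur)
        omega[active] += minimum_jerk_velocity(tau[active], amp) / dur
    return theta, omega


def generate_task(task: Task, profile: MovementProfile, seed: int | np.random.SeedSequence) -> TaskRecording:
    """Simulate one annotated two-IMU recording of ``task`` under ``profile``."""
    geom = TASK_GEOMETRY[Task(task)]
    rng = np.random.default_rng(seed)
    fs = FS_HZ

    lift_s, hold_s, ret_s = (p * profile.duration_scale for p in geom.phase_s)
    amp = geom.excursion_deg * profile.amplitude_scale

    n_pad = int(round(REST_PAD_S * fs))
    n_lift = max(int(round(lift_s * fs)), 4)
    n_hold = max(int(round(hold_s * fs)), 4)
    n_ret = max(int(round(ret_s * fs)), 4)

    t_lift = np.arange(n_lift) / fs
    t_hold = np.arange(n_hold) / fs
    t_ret = np.arange(n_ret) / fs

    lift_plan = _submovement_plan(rng, profile.n_submovements, n_lift / fs, amp)
    ret_plan = _submovement_plan(rng, profile.n_submovements, n_ret / fs, amp)

    th_lift, om_lift = _phase_angle(t_lift, lift_plan)
    th_ret_up, om_ret_up = _phase_angle(t_ret, ret_plan)
    th_ret = amp - th_ret_up          # mirrored descent
    om_ret = -om_ret_up

    osc = profile.hold_oscillation_amp * amp
    th_hold = amp + osc * np.sin(2 * np.pi * HOLD_OSC_HZ * t_hold)
    om_hold = osc * 2 * np.pi * HOLD_OSC_HZ * np.cos(2 * np.pi * HOLD_OSC_HZ * t_hold)

    theta = np.concatenate([
        np.zeros(n_pad), th_lift, th_hold, th_ret, np.zeros(n_pad)])
    omega = np.concatenate([
        np.zeros(n_pad), om_lift, om_hold, om_ret, np.zeros(n_pad)])

    s1 = (n_pad, n_pad + n_lift)
    s2 = (s1[1], s1[1] + n_hold)
    s3 = (s2[1], s2[1] + n_ret)
    annotation = SegmentAnnotation(complete=(s1[0], s3[1]), subtasks=(s1, s2, s3))

    arm = _sensor_channels(theta, omega, geom.axis, fs, profile, rng,
                           radius_m=ARM_RADIUS_M, lever=1.0, placement=Placement.ARM)
    wrist = _sensor_channels(theta, omega, geom.axis, fs, profile, rng,
                             radius_m=ARM_RADIUS_M * WRIST_LEVER, lever=WRIST_LEVER,
                             placement=Placement.WRIST)
    return TaskRecording(task=Task(task), arm=arm, wrist=wrist, annotation=annotation)


def _sensor_channels(
    theta_deg: np.ndarray,
    omega_deg_s: np.ndarray,
    axis: tuple[float, float, float],
    fs: float,
    profile: MovementProfile,
    rng: np.random.Generator,
    *,
    radius_m: float,
    lever: float,
    placement: Placement,
) -> SensorRecording:
    """Project the 1-DOF joint trajectory into six noisy sensor channels."""
    theta = np.radians(theta_deg)
    omega = np.radians(omega_deg_s) * lever          # rad/s at this sensor
    alpha_dot = np.gradient(omega, 1.0 / fs)         # rad/s^2

    # Gravity through the limb angle plus movement-induced components (in g).
    centripetal = radius_m * omega**2 / GRAVITY_M_S2
    tangential = radius_m * alpha_dot / GRAVITY_M_S2
    ax = np.cos(theta) + centripetal
    ay = np.sin(theta) + tangential
    az = 0.05 * np.sin(theta)

    accel = np.column_stack([ax, ay, az]) + rng.normal(0.0, profile.tremor_sd, (len(theta), 3))

    gyro_clean = np.outer(omega_deg_s * lever, np.asarray(axis))
    gyro = gyro_clean + rng.normal(0.0, profile.gyro_noise_sd, gyro_clean.shape)

    return SensorRecording(
        accel=TriaxialSignal(accel, fs),
        gyro=TriaxialSignal(gyro, fs),
        placement=placement,
    )


def _jittered(profile: MovementProfile, rng: np.random.Generator, jitter: float) -> MovementProfile:
    """Perturb the continuous scales of a profile by multiplicative lognormal jitter."""
    if jitter <= 0:
        return profile
    g = lambda: float(rng.lognormal(mean=0.0, sigma=jitter))
    return replace(
        profile,
        amplitude_scale=profile.amplitude_scale * g(),
        duration_scale=profile.duration_scale * g(),
        tremor_sd=profile.tremor_sd * g(),
        gyro_noise_sd=profile.gyro_noise_sd * g(),
        hold_oscillation_amp=profile.hold_oscillation_amp * g(),
    )


def generate_subject(
    subject_id: str,
    group: Group,
    profile: MovementProfile,
    seed: int | np.random.SeedSequence,
) -> Subject:
    """Simulate the five task recordings of one subject under a fixed profile."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    task_seeds = ss.spawn(len(Task))
    tasks = {
        task: generate_task(task, profile, task_seed)
        for task, task_seed in zip(Task, task_seeds)
    }
    return Subject(subject_id=subject_id, group=group, tasks=tasks)


def generate_cohort(
    n_fs: int,
    n_healthy: int,
    seed: int,
    profile_jitter: float = 0.1,
    profiles: tuple[MovementProfile, MovementProfile] | None = None,
) -> Cohort:
    """Simulate a labeled cohort of ``n_fs`` FS and ``n_healthy`` healthy subjects.

    Each subject's profile is the group default perturbed by multiplicative
    lognormal jitter with relative SD ``profile_jitter``; all per-subject seeds
    derive deterministically from the master ``seed``.
    """
    if n_fs < 1 or n_healthy < 1:
        raise ValueError("n_fs and n_healthy must be >= 1")
    healthy_profile, fs_profile = profiles if profiles is not None else default_profiles()
    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(n_fs + n_healthy)

    subjects = []
    for i in range(n_fs + n_healthy):
        is_fs = i < n_fs
        group = Group.FS if is_fs else Group.HEALTHY
        sid = f"{'FS' if is_fs else 'H'}{(i if is_fs else i - n_fs) + 1:02d}"
        ss = subject_seeds[i]
        jitter_rng = np.random.default_rng(ss.spawn(1)[0])
        profile = _jittered(fs_profile if is_fs else healthy_profile, jitter_rng, profile_jitter)
        subjects.append(generate_subject(sid, group, profile, ss))
    return Cohort(tuple(subjects))
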