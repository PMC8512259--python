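"""Synthetic heterogeneous accelerometer sessions.

Generates annotated triaxial wrist-acceleration streams for ten occupational
tasks (electrical panel work, hoisting, ladder climbing, lifting, overhead
work, pushing, sitting, standing, typing, walking) under controllable
cross-subject, cross-sensor and cross-scenario heterogeneity.

Each task is a synthetic surrogate, not a biomechanical model: a gravity
component along a task-specific wrist orientation plus a quasi-periodic
component with a task-specific fundamental frequency and amplitude, plus
Gaussian noise.  Subject heterogeneity perturbs the template with a per-axis
gain, a wrist-orientation rotation, and a tempo scaling of the fundamental
frequencies.  Sensor heterogeneity is modelled downstream of the ideal
motion: resampling onto a (possibly jittered) timestamp grid, per-axis scale
error and bias, conversion to the device's native unit, measurement noise,
and dropout gaps.  Two sensors worn simultaneously observe the *same* ideal
motion; their recordings differ only through their sensor models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import ScenarioError, UnitError, VocabularyError

#: Standard gravity used for all unit conversions, m/s^2.
STANDARD_GRAVITY = 9.80665

#: Task vocabulary: electrical panel, hoisting, ladder, lifting, overhead,
#: pushing, sitting, standing, typing, walking.
TASKS = ("EP", "H", "Ld", "Lf", "OH", "P", "St", "Sd", "Tp", "W")

UNITS = ("g64", "g", "m_s2")

# Per-task template parameters: wrist orientation (gravity direction in the
# sensor frame), fundamental frequency [Hz], amplitude of the quasi-periodic
# component [m/s^2].  Static postures (sitting, standing) have no periodic
# component; the dynamic tasks deliberately share nearby orientations or
# nearby fundamentals so that classes overlap the way noisy wrist data do,
# rather than being trivially separable.
_TASK_TEMPLATES: dict[str, tuple[tuple[float, float, float], float, float]] = {
    "EP": ((0.30, 0.85, 0.43), 1.7, 1.2),
    "H": ((0.10, -0.40, 0.91), 0.7, 2.2),
    "Ld": ((0.25, 0.70, 0.66), 1.3, 1.8),
    "Lf": ((0.00, -0.30, 0.95), 0.5, 2.0),
    "OH": ((0.35, 0.90, 0.26), 2.6, 1.0),
    "P": ((0.15, -0.45, 0.88), 1.0, 1.5),
    "St": ((0.90, 0.10, 0.42), 0.0, 0.0),
    "Sd": ((0.75, 0.05, 0.66), 0.0, 0.0),
    "Tp": ((0.45, -0.75, 0.48), 4.5, 0.6),
    "W": ((0.20, 0.60, 0.77), 2.0, 2.5),
}


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 32-bit child seeds from a master seed."""
    return [int(s) for s in np.random.SeedSequence(int(seed)).generate_state(n)]


def _unit_vector(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class SubjectProfile:
    """Idiosyncratic parameters of one subject.

    gain
        Per-axis positive multiplicative scale (unitless).
    rotation
        3x3 proper rotation matrix modelling wrist-orientation idiosyncrasy.
    tempo
        Positive scale applied to the task fundamental frequencies.
    noise_sd
        Standard deviation of the motion noise, m/s^2.
    """

    subject_id: str
    gain: np.ndarray
    rotation: np.ndarray
    tempo: float
    noise_sd: float

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "gain", g)
        object.__setattr__(self, "rotation", R)
        if g.shape != (3,) or np.any(g <= 0):
            raise ValueError("gain must be a length-3 positive vector")
        if R.shape != (3, 3) or np.linalg.norm(R.T @ R - np.eye(3)) >= 1e-10:
            raise ValueError("rotation must be orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if self.tempo <= 0:
            raise ValueError("tempo must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class Dropout:
    """Stochastic dropout: events per minute, duration ~ |N(mean, sd)|, s."""

    rate_per_min: float
    dur_mean_s: float
    dur_sd_s: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_per_min < 0 or self.dur_mean_s <= 0 or self.dur_sd_s < 0:
            raise ValueError("dropout durations and rate must be positive")


@dataclass(frozen=True)
class SensorModel:
    """Observation model of one wearable device.

    ``rate_hz`` is the (mean) sampling rate; ``jitter`` the fractional
    standard deviation of the inter-sample interval (0 = uniform sampling).
    ``bias`` and ``noise_sd`` are in the sensor's native unit,
    ``scale_error`` is multiplicative.  ``mounting_deg`` is a fixed
    device-frame misalignment (xyz Euler angles, degrees) relative to the
    reference device on the same wrist.  ``range_g`` is the accelerometer's
    full-scale measurement range in g; accelerations beyond it saturate.
    ``gap_intervals`` deletes explicit [start, end) spans deterministically,
    on top of stochastic ``dropout``.
    """

    sensor_id: str
    unit: str = "m_s2"
    rate_hz: float = 32.0
    jitter: float = 0.0
    bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale_error: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mounting_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    range_g: Optional[float] = None
    noise_sd: float = 0.0
    dropout: Optional[Dropout] = None
    gap_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit {self.unit!r}")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")
        for s, e in self.gap_intervals:
            if e <= s:
                raise ValueError("gap intervals must have positive duration")


@dataclass(frozen=True)
class ScenarioSpec:
    """Task-timeline layout of one session.

    ``separate``: each task occupies exactly one contiguous block, in
    canonical task order.  ``mixed``: short bouts of every task are shuffled
    within each of ``circuits`` repetitions; typing is excluded by design.
    ``bout_jitter`` is the fractional half-width of the uniform bout-duration
    distribution.  If ``total_s`` is given, drawn durations are rescaled so
    the annotated intervals tile [0, total_s] exactly.
    """

    kind: str
    task_set: tuple[str, ...] = TASKS
    bout_s: float = 60.0
    bout_jitter: float = 0.2
    circuits: int = 7
    total_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("separate", "mixed"):
            raise ScenarioError(f"unknown scenario kind {self.kind!r}")
        unknown = set(self.task_set) - set(TASKS)
        if unknown:
            raise VocabularyError(f"unknown task labels {sorted(unknown)}")
        if self.kind == "mixed" and "Tp" in self.task_set:
            raise ScenarioError("typing (Tp) is not performed in the mixed scenario")
        if self.bout_s <= 0 or not 0 <= self.bout_jitter < 1:
            raise ValueError("bout_s must be positive and 0 <= bout_jitter < 1")
        if self.kind == "mixed" and self.circuits < 1:
            raise ScenarioError("mixed scenario needs circuits >= 1")


@dataclass
class SensorRecording:
    """Timestamped triaxial acceleration stream in one declared unit.

    ``valid`` marks samples usable downstream; ``None`` means all valid
    (set by gap-aware resampling).
    """

    sensor_id: str
    unit: str
    timestamps: np.ndarray
    acc: np.ndarray
    nominal_rate_hz: float = 32.0
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit {self.unit!r}")
        if self.acc.shape != (self.timestamps.size, 3):
            raise ValueError("acc must be (n, 3) matching timestamps")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(~np.isfinite(self.acc)) or np.any(~np.isfinite(self.timestamps)):
            raise ValueError("recording contains non-finite values")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.timestamps.shape:
                raise ValueError("valid mask must match timestamps")

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass
class AnnotationTrack:
    """Ordered, non-overlapping labelled task intervals of one session."""

    intervals: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for label, start, end in self.intervals:
            if label not in TASKS:
                raise VocabularyError(f"unknown task label {label!r}")
            if start >= end:
                raise ValueError("interval start must precede end")
        ordered = sorted(self.intervals, key=lambda iv: iv[1])
        for (_, _, e0), (_, s1, _) in zip(ordered, ordered[1:]):
            if s1 < e0 - 1e-9:
                raise ValueError("annotation intervals overlap")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.intervals]

    @property
    def end_s(self) -> float:
        return max(e for _, _, e in self.intervals)


def make_cohort(
    n_subjects: int, heterogeneity_level: float, seed: int
) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles.

    The spread of gains (lognormal), wrist rotations (random axis, normal
    angle), tempos (lognormal) and noise levels scales linearly with
    ``heterogeneity_level``; level 0 yields identical profiles with unit
    gain, identity rotation and tempo 1.
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be nonnegative")
    if heterogeneity_level < 0:
        raise ValueError("heterogeneity_level must be nonnegative")
    lvl = float(heterogeneity_level)
    profiles = []
    for i, s in enumerate(_child_seeds(seed, max(n_subjects, 1))[:n_subjects]):
        rng = np.random.default_rng(s)
        gain = np.exp(rng.normal(0.0, 0.12 * lvl, size=3))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(0.0, 0.15 * lvl)
        rotation = Rotation.from_rotvec(axis * angle).as_matrix()
        tempo = float(np.exp(rng.normal(0.0, 0.08 * lvl)))
        noise_sd = float(1.2 * np.exp(rng.normal(0.0, 0.25 * lvl)))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1}",
                gain=gain,
                rotation=rotation,
                tempo=tempo,
                noise_sd=noise_sd,
            )
        )
    return profiles


def task_waveform(
    task: str, subject: SubjectProfile, t: np.ndarray, seed: int
) -> np.ndarray:
    """Ideal triaxial acceleration of one task bout, m/s^2.

    Template = gravity along the task orientation + task-specific
    quasi-periodic component (fundamental plus one harmonic) + Gaussian
    noise; the subject transform is ``rotation @ (gain * template)`` with
    frequencies scaled by ``tempo``.
    """
    if task not in _TASK_TEMPLATES:
        raise VocabularyError(f"unknown task label {task!r}")
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("time grid must be nonempty")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be increasing")
    orient, f0, amp = _TASK_TEMPLATES[task]
    u = _unit_vector(orient)
    rng = np.random.default_rng([int(seed), TASKS.index(task)])
    template = STANDARD_GRAVITY * u[None, :] * np.ones((t.size, 1))
    if amp > 0:
        # Two fixed movement directions roughly transverse to gravity, with
        # a slow random amplitude envelope so repetitions within a bout vary
        # the way human movement does.
        d1 = _unit_vector(np.cross(u, (0.0, 1.0, 0.1)))
        d2 = _unit_vector(np.cross(u, d1))
        f = f0 * subject.tempo
        ph1, ph2, ph3 = rng.uniform(0, 2 * np.pi, size=3)
        bout_amp = amp * float(np.exp(rng.normal(0.0, 0.2)))
        envelope = 1.0 + 0.3 * np.sin(2 * np.pi * 0.1 * t + ph3)
        template = template + (bout_amp * envelope)[:, None] * (
            np.sin(2 * np.pi * f * t + ph1)[:, None] * d1[None, :]
            + 0.35 * np.sin(2 * np.pi * 2 * f * t + ph2)[:, None] * d2[None, :]
        )
    template = template + rng.normal(0.0, subject.noise_sd, size=(t.size, 3))
    return (subject.gain[None, :] * template) @ subject.rotation.T


def _to_native(values_ms2: np.ndarray, unit: str) -> np.ndarray:
    if unit == "m_s2":
        return values_ms2
    if unit == "g":
        return values_ms2 / STANDARD_GRAVITY
    if unit == "g64":
        return values_ms2 / STANDARD_GRAVITY * 64.0
    raise UnitError(f"unknown unit {unit!r}")


def apply_sensor_model(
    ideal: SensorRecording, sensor: SensorModel, seed: int
) -> SensorRecording:
    """Observe an ideal m/s^2 series through a sensor model.

    Resamples the ideal signal onto the sensor's (possibly jittered)
    timestamp grid by linear interpolation, applies the multiplicative scale
    error, converts to the native unit, adds bias and measurement noise in
    native units, then deletes dropout intervals.  Timestamps remain
    strictly increasing.
    """
    if len(ideal) == 0:
        raise ValueError("ideal series is empty")
    if ideal.unit != "m_s2":
        raise UnitError("ideal series must be in m_s2")
    rng = np.random.default_rng([int(seed), 917])
    t0, t1 = float(ideal.timestamps[0]), float(ideal.timestamps[-1])
    if sensor.jitter == 0.0:
        n = int(np.floor((t1 - t0) * sensor.rate_hz + 1e-9)) + 1
        tt = t0 + np.arange(n) / sensor.rate_hz
    else:
        mean_dt = 1.0 / sensor.rate_hz
        n_est = int(np.ceil((t1 - t0) * sensor.rate_hz * 1.6)) + 16
        dts = mean_dt * np.clip(
            rng.normal(1.0, sensor.jitter, size=n_est), 0.2, None
        )
        tt = t0 + np.concatenate([[0.0], np.cumsum(dts)])
        tt = tt[tt <= t1 + 1e-12]
    acc = np.column_stack(
        [np.interp(tt, ideal.timestamps, ideal.acc[:, i]) for i in range(3)]
    )
    if any(sensor.mounting_deg):
        R = Rotation.from_euler("xyz", sensor.mounting_deg, degrees=True).as_matrix()
        acc = acc @ R.T
    if sensor.range_g is not None:
        limit = sensor.range_g * STANDARD_GRAVITY
        acc = np.clip(acc, -limit, limit)
    acc = acc * np.asarray(sensor.scale_error, dtype=float)[None, :]
    acc = _to_native(acc, sensor.unit)
    acc = acc + np.asarray(sensor.bias, dtype=float)[None, :]
    if sensor.noise_sd > 0:
        acc = acc + rng.normal(0.0, sensor.noise_sd, size=acc.shape)
    keep = np.ones(tt.size, dtype=bool)
    gaps = list(sensor.gap_intervals)
    if sensor.dropout is not None and sensor.dropout.rate_per_min > 0:
        span_min = (t1 - t0) / 60.0
        n_events = rng.poisson(sensor.dropout.rate_per_min * span_min)
        starts = rng.uniform(t0, t1, size=n_events)
        durs = np.abs(
            rng.normal(sensor.dropout.dur_mean_s, sensor.dropout.dur_sd_s, n_events)
        )
        durs = np.clip(durs, 0.05, None)
        gaps.extend(zip(starts, starts + durs))
    for s, e in gaps:
        keep &= ~((tt >= s) & (tt < e))
    return SensorRecording(
        sensor_id=sensor.sensor_id,
        unit=sensor.unit,
        timestamps=tt[keep],
        acc=acc[keep],
        nominal_rate_hz=sensor.rate_hz,
    )


def _draw_intervals(
    scenario: ScenarioSpec, rng: np.random.Generator
) -> list[tuple[str, float, float]]:
    if scenario.kind == "separate":
        tasks = [t for t in TASKS if t in scenario.task_set]
    else:
        tasks = []
        ordered = [t for t in TASKS if t in scenario.task_set]
        for _ in range(scenario.circuits):
            tasks.extend(rng.permutation(ordered).tolist())
    durs = scenario.bout_s * rng.uniform(
        1 - scenario.bout_jitter, 1 + scenario.bout_jitter, size=len(tasks)
    )
    if scenario.total_s is not None:
        durs *= scenario.total_s / durs.sum()
    edges = np.concatenate([[0.0], np.cumsum(durs)])
    return [(task, float(s), float(e)) for task, s, e in zip(tasks, edges, edges[1:])]


def simulate_ideal_session(
    subject: SubjectProfile, scenario: ScenarioSpec, seed: int
) -> tuple[SensorRecording, AnnotationTrack]:
    """Ideal (noise-free sensing) session on the reference 32 Hz grid, m/s^2.

    Both wearables observe this one series; apply sensor models afterwards.
    """
    layout_seed, *bout_seeds_head = _child_seeds(seed, 2)
    rng = np.random.default_rng(layout_seed)
    intervals = _draw_intervals(scenario, rng)
    track = AnnotationTrack(intervals)
    total = track.end_s
    t = np.arange(0.0, total, 1.0 / 32.0)
    acc = np.zeros((t.size, 3))
    bout_seeds = _child_seeds(bout_seeds_head[0], len(intervals))
    for (label, start, end), bseed in zip(intervals, bout_seeds):
        idx = (t >= start - 1e-9) & (t < end - 1e-9)
        if idx.any():
            acc[idx] = task_waveform(label, subject, t[idx], bseed)
    rec = SensorRecording(
        sensor_id="ideal", unit="m_s2", timestamps=t, acc=acc, nominal_rate_hz=32.0
    )
    return rec, track


def simulate_session(
    subject: SubjectProfile,
    sensor: SensorModel,
    scenario: ScenarioSpec,
    seed: int,
) -> tuple[SensorRecording, AnnotationTrack]:
    """Simulate one annotated session as observed by one sensor."""
    ideal_seed, sensor_seed = _child_seeds(seed, 2)
    ideal, track = simulate_ideal_session(subject, scenario, ideal_seed)
    return apply_sensor_model(ideal, sensor, sensor_seed), track
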