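"""Unit conversion, gap-aware resampling and fixed-size windowing.

The two simulated wearables disagree in measurement unit (g/64 vs g vs
m/s^2) and in sampling regularity, so every recording is first converted to
m/s^2 and linearly resampled onto a uniform 32 Hz grid.  Grid points whose
bracketing raw gap exceeds 1 s are marked invalid rather than interpolated,
to avoid manufacturing data inside long dropouts.  Annotated intervals are
then tiled with non-overlapping windows (10 s = 320 samples or
4 s = 128 samples); a window is emitted only if it lies entirely inside a
single annotated interval and touches no invalid sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, UnitError
from .synth import (
    STANDARD_GRAVITY,
    AnnotationTrack,
    SensorRecording,
)

_EPS = 1e-9


@dataclass
class LabelledWindow:
    """Fixed-length single-task window on the uniform 32 Hz grid, m/s^2."""

    label: str
    samples: np.ndarray
    start_s: float
    subject: str = ""
    sensor: str = ""
    scenario: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be (n, 3)")
        if np.any(~np.isfinite(self.samples)):
            raise ValueError("window contains non-finite samples")


def convert_units(recording: SensorRecording) -> SensorRecording:
    """Convert a recording to m/s^2 (g64 -> /64 * g0, g -> * g0)."""
    if recording.unit == "m_s2":
        factor = 1.0
    elif recording.unit == "g":
        factor = STANDARD_GRAVITY
    elif recording.unit == "g64":
        factor = STANDARD_GRAVITY / 64.0
    else:  # pragma: no cover - SensorRecording validates units
        raise UnitError(f"unknown unit {recording.unit!r}")
    return SensorRecording(
        sensor_id=recording.sensor_id,
        unit="m_s2",
        timestamps=recording.timestamps.copy(),
        acc=recording.acc * factor,
        nominal_rate_hz=recording.nominal_rate_hz,
        valid=None if recording.valid is None else recording.valid.copy(),
    )


def regularize_sampling(
    recording: SensorRecording, rate: float = 32.0, max_gap: float = 1.0
) -> SensorRecording:
    """Resample onto a uniform grid at ``rate``, masking long-gap spans.

    The output grid spans [t_first, t_last] at exact 1/rate spacing.  Each
    grid point is linearly interpolated from its bracketing raw samples; if
    the bracketing raw gap exceeds ``max_gap`` seconds the point is marked
    invalid instead.  Grid points coinciding with a raw sample inherit that
    sample's validity, which makes the operation idempotent.
    """
    raw_t = recording.timestamps
    if raw_t.size < 2:
        raise InsufficientDataError("need at least 2 samples to resample")
    t0, t1 = float(raw_t[0]), float(raw_t[-1])
    n = int(np.floor((t1 - t0) * rate + _EPS)) + 1
    grid = t0 + np.arange(n) / rate
    acc = np.column_stack(
        [np.interp(grid, raw_t, recording.acc[:, i]) for i in range(3)]
    )
    left = np.clip(np.searchsorted(raw_t, grid, side="right") - 1, 0, raw_t.size - 2)
    gap = raw_t[left + 1] - raw_t[left]
    valid = gap <= max_gap + _EPS
    # Points landing exactly on a raw sample are valid regardless of the
    # neighbouring gap (they are measurements, not interpolations) unless the
    # raw sample itself was already masked.
    exact = np.isclose(grid, raw_t[left], atol=1e-6 / rate) | np.isclose(
        grid, raw_t[np.clip(left + 1, 0, raw_t.size - 1)], atol=1e-6 / rate
    )
    nearest = np.clip(np.searchsorted(raw_t, grid), 0, raw_t.size - 1)
    on_left = np.isclose(grid, raw_t[left], atol=1e-6 / rate)
    exact_idx = np.where(on_left, left, nearest)
    if recording.valid is None:
        valid = valid | exact
    else:
        raw_valid = recording.valid
        valid = np.where(
            exact,
            raw_valid[exact_idx],
            valid & raw_valid[left] & raw_valid[np.clip(left + 1, 0, raw_t.size - 1)],
        )
    return SensorRecording(
        sensor_id=recording.sensor_id,
        unit=recording.unit,
        timestamps=grid,
        acc=acc,
        nominal_rate_hz=rate,
        valid=valid,
    )


def segment(
    recording: SensorRecording,
    annotations: AnnotationTrack,
    window_s: float,
    rate: float = 32.0,
    subject: str = "",
    scenario: str = "",
) -> list[LabelledWindow]:
    """Tile annotated intervals with non-overlapping single-task windows.

    Windows are aligned to each interval's start; trailing partial windows
    and windows containing any invalid sample are dropped.
    """
    n_samples = window_s * rate
    if abs(n_samples - round(n_samples)) > _EPS:
        raise ValueError("window_s * rate must be an integer sample count")
    n_samples = int(round(n_samples))
    t = recording.timestamps
    if t.size < 2 or np.any(np.abs(np.diff(t) - 1.0 / rate) > 1e-6):
        raise ValueError("recording must be uniform at the target rate")
    t0 = float(t[0])
    valid = (
        np.ones(t.size, dtype=bool) if recording.valid is None else recording.valid
    )
    windows: list[LabelledWindow] = []
    for label, start, end in annotations.intervals:
        w_start = start
        while w_start + window_s <= end + _EPS:
            i0 = int(np.ceil((w_start - t0) * rate - 1e-6))
            if i0 >= 0 and i0 + n_samples <= t.size:
                in_window = t[i0] >= w_start - _EPS and (
                    t[i0 + n_samples - 1] < w_start + window_s + _EPS
                )
                if in_window and valid[i0 : i0 + n_samples].all():
                    windows.append(
                        LabelledWindow(
                            label=label,
                            samples=recording.acc[i0 : i0 + n_samples],
                            start_s=w_start,
                            subject=subject,
                            sensor=recording.sensor_id,
                            scenario=scenario,
                        )
                    )
            w_start += window_s
    return windows
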