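import numpy as np
import pytest

from hetero_har.synth import (
    ScenarioSpec,
    SensorModel,
    SensorRecording,
    SubjectProfile,
    TASKS,
)


@pytest.fixture
def identity_subject() -> SubjectProfile:
    return SubjectProfile(
        subject_id="ID",
        gain=np.ones(3),
        rotation=np.eye(3),
        tempo=1.0,
        noise_sd=0.0,
    )


@pytest.fixture
def noisy_identity_subject() -> SubjectProfile:
    return SubjectProfile(
        subject_id="IDn",
        gain=np.ones(3),
        rotation=np.eye(3),
        tempo=1.0,
        noise_sd=0.5,
    )


@pytest.fixture
def identity_sensor_model() -> SensorModel:
    return SensorModel(sensor_id="ID", unit="m_s2", rate_hz=32.0)


@pytest.fixture
def short_separate_scenario() -> ScenarioSpec:
    """All ten tasks in short contiguous blocks (fast to simulate)."""
    return ScenarioSpec("separate", TASKS, bout_s=4.0, bout_jitter=0.0)


def uniform_recording(
    values: np.ndarray, rate: float = 32.0, unit: str = "m_s2", t0: float = 0.0
) -> SensorRecording:
    values = np.asarray(values, dtype=float)
    t = t0 + np.arange(values.shape[0]) / rate
    return SensorRecording(
        sensor_id="T", unit=unit, timestamps=t, acc=values, nominal_rate_hz=rate
    )
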