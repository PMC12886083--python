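import numpy as np
import pytest
from hypothesis import settings

import ventwave as vw

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def square_wave_recording() -> vw.WaveformRecording:
    """One idealized square-wave breath at 256 Hz.

    Flow +30 L/min on [1, 2) s and -30 L/min on [2, 3) s; pressure 20 cmH2O
    on [1, 2.2) s; 6 s total. With the tuned profile this breath starts at
    ~0.7 s, its active phase ends at ~3.833 s, and both volumes are 500 ml.
    """
    fs = 256
    n = 6 * fs
    t = np.arange(n) / fs
    flow = np.zeros(n)
    flow[(t >= 1.0) & (t < 2.0)] = 30.0
    flow[(t >= 2.0) & (t < 3.0)] = -30.0
    pressure = np.zeros(n)
    pressure[(t >= 1.0) & (t < 2.2)] = 20.0
    return vw.WaveformRecording(flow=flow, pressure=pressure, sampling_rate=fs)


def make_breath_train(
    n_breaths: int = 5,
    period: float = 6.0,
    flow_amp: float = 30.0,
    pressure_amp: float = 20.0,
    fs: float = 256.0,
    lead_in: float = 1.0,
    insp_time: float = 1.0,
    pressure_time: float = 1.2,
    tail: float = 4.0,
) -> vw.WaveformRecording:
    """Train of idealized square-wave breaths for detection tests."""
    duration = lead_in + (n_breaths - 1) * period + insp_time * 2 + tail
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    flow = np.zeros(n)
    pressure = np.zeros(n)
    for k in range(n_breaths):
        ts = lead_in + k * period
        flow[(t >= ts) & (t < ts + insp_time)] = flow_amp
        flow[(t >= ts + insp_time) & (t < ts + 2 * insp_time)] = -flow_amp
        pressure[(t >= ts) & (t < ts + pressure_time)] = pressure_amp
    return vw.WaveformRecording(flow=flow, pressure=pressure, sampling_rate=fs)


@pytest.fixture
def breath_train():
    return make_breath_train


def random_recording(seed: int, fs: float = 64.0) -> vw.WaveformRecording:
    """Random piecewise waveform for oracle-equivalence fuzzing (<= 10 s)."""
    rng = np.random.default_rng(seed)
    duration = float(rng.uniform(5.0, 10.0))
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    pressure = np.zeros(n)
    for _ in range(rng.integers(1, 7)):
        start = rng.uniform(0.0, duration)
        width = rng.uniform(0.05, 1.5)
        pressure[(t >= start) & (t < start + width)] += rng.uniform(0.5, 14.0)
    flow = rng.normal(0.0, 2.0, n)
    for _ in range(rng.integers(1, 7)):
        start = rng.uniform(0.0, duration)
        width = rng.uniform(0.1, 2.0)
        flow[(t >= start) & (t < start + width)] += rng.uniform(-40.0, 40.0)
    return vw.WaveformRecording(flow=flow, pressure=pressure, sampling_rate=fs)


def random_params(seed: int) -> vw.AlgorithmParams:
    """Random parameter vector drawn from the calibration grid values."""
    rng = np.random.default_rng(seed + 10_000)
    return vw.AlgorithmParams(
        pressure_threshold_A=float(rng.choice([1.0, 2.0, 5.0, 8.0, 10.0])),
        pressure_duration_B=float(rng.choice([0.1, 0.2, 0.3, 0.4, 0.5])),
        ventilation_lead_C=float(rng.choice([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])),
        abs_flow_threshold_D=float(rng.choice([-1.0, 1.0, 5.0, 10.0])),
        inactive_delay_E=float(rng.choice([0.0, 0.1, 0.2, 0.3])),
    )
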