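"""Simulated ventilator waveforms with CPR artefacts, leak, and ground truth.

A single-compartment linear lung (resistance R in cmH2O/(L/s), compliance C
in ml/cmH2O, passive time constant R*C/1000 seconds) stands in for the
physical test lung of the bench setup this emulates:

* volume-controlled breaths deliver a constant inspiratory flow Q = VT/Ti
  for the inspiratory time Ti, giving airway pressure
  p = PEEP + R*Q + V/C (V = insufflated volume above rest);
* pressure-controlled breaths drive airway pressure to the set inspiratory
  pressure for Ti, giving an exponentially decaying inflow;
* expiration is passive, V decaying exponentially with time constant R*C;
* an airway leak diverts a fixed fraction of the expired volume around the
  flow sensor, so the sensor sees (1 - leak) of each exhalation;
* chest compressions superimpose a biphasic (push/recoil) flow oscillation
  displacing ``compression_volume`` ml per cycle at 110/min, with the
  corresponding pressure oscillation of the lung model — continuously in
  the asynchronous regime, or in 30-compression blocks alternating with
  2-breath pauses in the synchronous (30:2) regime;
* optional Gaussian sensor noise is deterministic given the seed.

Ground truth (start time, delivered inspiratory volume, expired volume,
peak pressure, set rate per breath) is recorded from the model state, never
from the generated waveform. The CO2 channel is a simple expiratory plateau
placeholder (no gas-exchange kinetics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ParameterError, WaveformRecording

__all__ = [
    "SimulationConfig",
    "simulate_run",
    "add_compressions",
    "generate_dataset",
    "demo_configs",
    "GROUND_TRUTH_COLUMNS",
]

GROUND_TRUTH_COLUMNS = [
    "breath_index",
    "start_time_s",
    "insp_volume_ml",
    "exp_volume_ml",
    "peak_pressure_cmh2o",
    "set_rate_per_min",
]

#: Quiet interval between the second synchronous insufflation's inspiratory
#: phase and the resumption of compressions, long enough for passive
#: exhalation to finish for the demo lungs (>= 5 time constants).
_SYNC_EXHALE_GAP = 2.5

#: Pre-roll before the first scheduled breath: recordings begin before
#: ventilation starts, so the first breath's lead is never clipped by the
#: record edge.
_VENT_START = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated run.

    ``tidal_volume`` (ml) applies in volume-controlled mode,
    ``insp_pressure`` (cmH2O) in pressure-controlled mode. ``rate`` is the
    set ventilation rate (ignored for the synchronous regime, where the 30:2
    block structure dictates breath timing). Compression depth is expressed
    as the displaced volume per cycle in ml.
    """

    mode: str = "volume"  # "volume" | "pressure"
    tidal_volume: float = 500.0
    insp_pressure: float | None = None
    rate: float = 10.0
    insp_time: float = 1.0
    compliance: float = 50.0
    resistance: float = 10.0
    peep: float = 0.0
    cpr_mode: str = "none"  # "none" | "asynchronous" | "synchronous"
    compression_rate: float = 110.0
    compression_volume: float = 40.0
    leak_fraction: float = 0.0
    noise_sd_flow: float = 0.0
    noise_sd_pressure: float = 0.0
    duration: float = 120.0
    sampling_rate: float = 256.0
    seed: int = 0
    include_co2: bool = True
    run_id: str = "run"

    def __post_init__(self) -> None:
        if self.mode not in ("volume", "pressure"):
            raise ParameterError(f"mode must be 'volume' or 'pressure', got {self.mode!r}")
        if self.cpr_mode not in ("none", "asynchronous", "synchronous"):
            raise ParameterError(f"unknown cpr_mode {self.cpr_mode!r}")
        if self.mode == "pressure" and self.insp_pressure is None:
            raise ParameterError("pressure mode requires insp_pressure")
        if not self.rate > 0:
            raise ParameterError("rate must be > 0")
        if not self.duration > 0:
            raise ParameterError("duration must be > 0")
        if not 0 <= self.leak_fraction < 1:
            raise ParameterError("leak_fraction must be in [0, 1)")
        if not (self.compliance > 0 and self.resistance > 0):
            raise ParameterError("compliance and resistance must be > 0")
        if not self.insp_time > 0:
            raise ParameterError("insp_time must be > 0")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be > 0")

    @property
    def time_constant(self) -> float:
        """Passive expiratory time constant R*C, in seconds."""
        return self.resistance * self.compliance / 1000.0


def _sync_schedule(config: SimulationConfig) -> tuple[list[float], list[tuple[float, float]]]:
    """Breath start times and compression intervals for the 30:2 regime."""
    tc = 60.0 / config.compression_rate
    comp_block = 30.0 * tc
    gap = config.insp_time + _SYNC_EXHALE_GAP
    starts: list[float] = []
    comp_intervals: list[tuple[float, float]] = []
    b0 = 0.0
    while True:
        t1 = b0 + comp_block
        t2 = t1 + gap
        if t2 + gap > config.duration:
            comp_intervals.append((b0, min(b0 + comp_block, config.duration)))
            break
        comp_intervals.append((b0, t1))
        starts.extend((t1, t2))
        b0 = t2 + gap
    return starts, comp_intervals


def _breath_starts(config: SimulationConfig) -> list[float]:
    if config.cpr_mode == "synchronous":
        return _sync_schedule(config)[0]
    period = 60.0 / config.rate
    if config.duration < _VENT_START:
        return []
    n_breaths = 1 + int(np.floor((config.duration - _VENT_START) / period + 1e-9))
    return [_VENT_START + i * period for i in range(n_breaths)]


def simulate_run(config: SimulationConfig) -> tuple[WaveformRecording, pd.DataFrame]:
    """Simulate one run; returns the recording and its per-breath ground truth."""
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    flow_ls = np.zeros(n)  # ventilator flow at the sensor, L/s, + toward lung
    pressure = np.full(n, config.peep, dtype=float)
    co2 = np.zeros(n) if config.include_co2 else None
    tau = config.time_constant
    C, R = config.compliance, config.resistance

    starts = _breath_starts(config)
    truth_rows = []
    V = 0.0  # lung volume above the PEEP equilibrium, ml
    for k, ts in enumerate(starts):
        te = ts + config.insp_time
        next_ts = starts[k + 1] if k + 1 < len(starts) else config.duration
        i0 = int(round(ts * fs))
        i1 = min(n, int(round(te * fs)))
        i2 = min(n, int(round(next_ts * fs)))

        # Flow samples represent the volume moved during each sample period
        # (successive differences of the model volume), so integrating the
        # waveform conserves volume exactly.
        tt = np.arange(i0, i1) / fs - ts
        if config.mode == "volume":
            Q = config.tidal_volume / 1000.0 / config.insp_time  # L/s
            v_arr = V + Q * 1000.0 * tt
            flow_ls[i0:i1] = Q
            pressure[i0:i1] = config.peep + R * Q + v_arr / C
            v_end = V + config.tidal_volume
            insp_true = config.tidal_volume
            peak_true = config.peep + R * Q + v_end / C
        else:
            v_target = C * (config.insp_pressure - config.peep)
            tt_edges = np.arange(i0, i1 + 1) / fs - ts
            v_edges = v_target + (V - v_target) * np.exp(-tt_edges / tau)
            flow_ls[i0:i1] = np.diff(v_edges) * fs / 1000.0
            pressure[i0:i1] = config.insp_pressure
            v_end = v_target + (V - v_target) * np.exp(-config.insp_time / tau)
            insp_true = v_end - V
            peak_true = float(config.insp_pressure)

        tt2_edges = np.arange(i1, i2 + 1) / fs - te
        v_exp_edges = v_end * np.exp(-tt2_edges / tau)
        flow_ls[i1:i2] = np.diff(v_exp_edges) * fs / 1000.0 * (1.0 - config.leak_fraction)
        pressure[i1:i2] = config.peep
        if co2 is not None:
            co2[i1:i2] = 38.0 * (1.0 - np.exp(-tt2_edges[:-1] / 0.25))
        V = v_end * np.exp(-(next_ts - te) / tau)

        truth_rows.append(
            {
                "breath_index": k,
                "start_time_s": ts,
                "insp_volume_ml": insp_true,
                "exp_volume_ml": (1.0 - config.leak_fraction) * insp_true,
                "peak_pressure_cmh2o": peak_true,
                "set_rate_per_min": (
                    np.nan if config.cpr_mode == "synchronous" else config.rate
                ),
            }
        )

    recording = WaveformRecording(
        flow=flow_ls * 60.0,
        pressure=pressure,
        sampling_rate=fs,
        co2=co2,
        run_id=config.run_id,
    )
    if config.cpr_mode != "none":
        recording = add_compressions(recording, config)
    if config.noise_sd_flow > 0 or config.noise_sd_pressure > 0:
        rng = np.random.default_rng(config.seed)
        flow = recording.flow + rng.normal(0.0, config.noise_sd_flow, n)
        pres = recording.pressure + rng.normal(0.0, config.noise_sd_pressure, n)
        recording = replace(recording, flow=flow, pressure=pres)

    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    return recording, truth


def add_compressions(
    recording: WaveformRecording, config: SimulationConfig
) -> WaveformRecording:
    """Superimpose the chest-compression artefact on a recording.

    Each compression cycle displaces ``compression_volume`` ml through the
    lung model as a raised-cosine push with passive recoil, i.e. a biphasic
    flow oscillation with zero net displacement per cycle, plus the matching
    pressure oscillation (elastic component d/C and resistive component
    R*q). Ground-truth volumes are unaffected: the ventilator settings
    define the truth, the compressions only displace gas.
    """
    if config.cpr_mode == "none":
        warnings.warn("cpr_mode is 'none'; add_compressions is a no-op", stacklevel=2)
        return recording
    t = recording.times() - recording.start_time
    tc = 60.0 / config.compression_rate
    if config.cpr_mode == "asynchronous":
        intervals = [(0.0, recording.duration)]
    else:
        intervals = _sync_schedule(config)[1]

    vc = config.compression_volume
    d = np.zeros(recording.n_samples)  # displaced volume, ml
    q = np.zeros(recording.n_samples)  # compression flow at the sensor, L/s
    for lo, hi in intervals:
        mask = (t >= lo) & (t < hi)
        theta = 2.0 * np.pi * (t[mask] - lo) / tc
        d[mask] = 0.5 * vc * (1.0 - np.cos(theta))
        q[mask] = -(vc * np.pi / tc) * np.sin(theta) / 1000.0
    flow = recording.flow + 60.0 * q
    pressure = recording.pressure + d / config.compliance + config.resistance * q
    return replace(recording, flow=flow, pressure=pressure)


def generate_dataset(
    configs: Sequence[SimulationConfig], out_dir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every config and write waveforms + manifest + ground truth.

    Writes one ``<run_id>.csv`` waveform per run, a ``manifest.csv`` whose
    per-run reference values are derived from the ground truth, and a pooled
    ``groundtruth.csv``. Fully reproducible from the configs' seeds. Returns
    the manifest and ground-truth frames.
    """
    if not configs:
        raise ParameterError("at least one SimulationConfig is required")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        if not out_dir.is_dir():
            raise OSError("not a directory")
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    manifest_rows = []
    truth_frames = []
    for config in configs:
        recording, truth = simulate_run(config)
        waveform = pd.DataFrame(
            {"flow_lpm": recording.flow, "pressure_cmh2o": recording.pressure}
        )
        if recording.co2 is not None:
            waveform["co2"] = recording.co2
        waveform.to_csv(out_dir / f"{config.run_id}.csv", index=False, float_format="%.8g")
        manifest_rows.append(
            {
                "run_id": config.run_id,
                "waveform": f"{config.run_id}.csv",
                "mode": config.mode,
                "cpr_mode": config.cpr_mode,
                "set_insp_volume": float(truth["insp_volume_ml"].median()),
                "set_exp_volume": float(truth["exp_volume_ml"].median()),
                "set_peak_pressure": float(truth["peak_pressure_cmh2o"].median()),
                "set_rate": (
                    np.nan if config.cpr_mode == "synchronous" else config.rate
                ),
                "duration": config.duration,
                "exclude_exp": False,
            }
        )
        truth = truth.copy()
        truth.insert(0, "run_id", config.run_id)
        truth_frames.append(truth)

    manifest = pd.DataFrame(manifest_rows)
    truth_all = pd.concat(truth_frames, ignore_index=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False, float_format="%.10g")
    truth_all.to_csv(out_dir / "groundtruth.csv", index=False, float_format="%.10g")
    return manifest, truth_all


# Demo dataset layout: 37 two-minute runs (20 without compressions, 10
# asynchronous, 7 synchronous 30:2) spanning tidal volumes 177-612 ml, peak
# pressures in the low-to-mid teens through ~45 cmH2O, and rates 10-30/min in
# both ventilator modes. Per-run compliance/resistance are chosen so that
# volume-mode airway pressure crosses the tuned detection threshold early
# enough in the inspiration to sustain it, as on the bench this emulates.
_VOLUME_RUNS = [
    # (VT ml, rate/min, Ti s, C ml/cmH2O, R cmH2O/(L/s), leak)
    (177.0, 30.0, 0.6, 11.0, 5.0, 0.0),
    (225.0, 25.0, 0.7, 15.0, 5.0, 0.0),
    (275.0, 20.0, 0.8, 18.0, 8.0, 0.0),
    (325.0, 20.0, 0.9, 22.0, 8.0, 0.0),
    (375.0, 15.0, 1.0, 28.0, 10.0, 0.0),
    (425.0, 15.0, 1.0, 30.0, 10.0, 0.0),
    (475.0, 12.0, 1.0, 35.0, 10.0, 0.0),
    (500.0, 10.0, 1.0, 50.0, 10.0, 0.1),
    (550.0, 12.0, 1.1, 40.0, 10.0, 0.0),
    (612.0, 10.0, 1.2, 40.0, 10.0, 0.2),
]
_PRESSURE_RUNS = [
    # (P cmH2O, rate/min, C ml/cmH2O, leak)
    (13.0, 20.0, 30.0, 0.0),
    (16.0, 20.0, 30.0, 0.0),
    (20.0, 25.0, 20.0, 0.0),
    (24.0, 15.0, 25.0, 0.0),
    (28.0, 20.0, 20.0, 0.0),
    (32.0, 25.0, 18.0, 0.15),
    (36.0, 15.0, 16.0, 0.0),
    (40.0, 20.0, 14.0, 0.0),
    (43.0, 10.0, 13.0, 0.0),
    (45.0, 15.0, 12.0, 0.0),
]
_ASYNC_RUNS = [400.0, 360.0, 380.0, 400.0, 420.0, 440.0, 400.0, 390.0, 410.0, 430.0]
_SYNC_RUNS = [500.0, 480.0, 520.0, 500.0, 460.0, 540.0, 500.0]


def demo_configs(seed: int = 0) -> list[SimulationConfig]:
    """The 37-run demo dataset: 20 no-CPR, 10 asynchronous, 7 synchronous."""
    configs: list[SimulationConfig] = []
    for i, (vt, rate, ti, c, r, leak) in enumerate(_VOLUME_RUNS):
        configs.append(
            SimulationConfig(
                mode="volume",
                tidal_volume=vt,
                rate=rate,
                insp_time=ti,
                compliance=c,
                resistance=r,
                leak_fraction=leak,
                seed=seed + len(configs),
                run_id=f"vc_none_{i:02d}",
            )
        )
    for i, (p, rate, c, leak) in enumerate(_PRESSURE_RUNS):
        configs.append(
            SimulationConfig(
                mode="pressure",
                insp_pressure=p,
                rate=rate,
                insp_time=1.0,
                compliance=c,
                resistance=10.0,
                leak_fraction=leak,
                seed=seed + len(configs),
                run_id=f"pc_none_{i:02d}",
            )
        )
    for i, vt in enumerate(_ASYNC_RUNS):
        configs.append(
            SimulationConfig(
                mode="volume",
                tidal_volume=vt,
                rate=10.0,
                insp_time=1.0,
                compliance=30.0,
                resistance=10.0,
                cpr_mode="asynchronous",
                seed=seed + len(configs),
                run_id=f"vc_async_{i:02d}",
            )
        )
    for i, vt in enumerate(_SYNC_RUNS):
        configs.append(
            SimulationConfig(
                mode="volume",
                tidal_volume=vt,
                rate=10.0,
                insp_time=1.0,
                compliance=50.0,
                resistance=10.0,
                cpr_mode="synchronous",
                seed=seed + len(configs),
                run_id=f"vc_sync_{i:02d}",
            )
        )
    return configs
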