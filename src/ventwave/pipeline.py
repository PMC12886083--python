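"""End-to-end convenience pipelines tying detection, measures and evaluation."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import (
    AlgorithmParams,
    BreathEvent,
    WaveformRecording,
    read_waveform,
    write_breath_table,
)
from .detect import segment_recording
from .evaluation import summarize_by_group
from .measures import BreathMeasures, measure_breaths
from .simulate import SimulationConfig, simulate_run
from .tuning import RunSettings, match_breaths

__all__ = [
    "analyze_recording",
    "detect_file",
    "pairs_dataframe",
    "evaluate_runs",
    "run_demo_dataset",
    "settings_from_truth",
]


def analyze_recording(
    recording: WaveformRecording, params: AlgorithmParams | None = None
) -> tuple[list[BreathEvent], list[BreathMeasures]]:
    """Segment a recording and compute all per-breath measures."""
    params = params if params is not None else AlgorithmParams()
    events, _ = segment_recording(recording, params)
    return events, measure_breaths(recording, events, params)


def detect_file(
    input_path: str | Path,
    output_path: str | Path,
    params: AlgorithmParams | None = None,
    sampling_rate: float = 256.0,
    trace_path: str | Path | None = None,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Run detection on a waveform CSV and write the breath table."""
    params = params if params is not None else AlgorithmParams()
    recording = read_waveform(input_path, sampling_rate=sampling_rate, column_map=column_map)
    events, trace = segment_recording(recording, params)
    measures = measure_breaths(recording, events, params)
    write_breath_table(events, measures, output_path)
    if trace_path is not None:
        pd.DataFrame(trace.candidates, columns=["time_s", "status"]).to_csv(
            trace_path, index=False, float_format="%.10g"
        )
    from .core import read_breath_table

    return read_breath_table(output_path)


def pairs_dataframe(
    runs: Sequence[tuple[Sequence[BreathEvent], Sequence[BreathMeasures], RunSettings]],
    include_missed: bool = False,
) -> pd.DataFrame:
    """Pool per-breath (measured, set) pairs over runs into one frame.

    Evaluation pairs only detected breaths by default; the miss penalty is a
    tuning-objective device.
    """
    rows = []
    for events, measures, settings in runs:
        for pair in match_breaths(events, measures, settings, include_missed=include_missed):
            rows.append(
                {
                    "run_id": settings.run_id,
                    "cpr_mode": settings.cpr_mode,
                    "measure": pair.measure,
                    "measured": pair.measured,
                    "set_value": pair.set_value,
                }
            )
    return pd.DataFrame(rows, columns=["run_id", "cpr_mode", "measure", "measured", "set_value"])


def evaluate_runs(
    runs: Sequence[tuple[Sequence[BreathEvent], Sequence[BreathMeasures], RunSettings]],
) -> pd.DataFrame:
    """Agreement summary table, one row per (cpr_mode, measure)."""
    return summarize_by_group(pairs_dataframe(runs))


def settings_from_truth(config: SimulationConfig, truth: pd.DataFrame) -> RunSettings:
    """Reference run settings derived from a simulated run's ground truth."""
    return RunSettings(
        run_id=config.run_id,
        mode=config.mode,
        cpr_mode=config.cpr_mode,
        set_insp_volume=float(truth["insp_volume_ml"].median()),
        set_exp_volume=float(truth["exp_volume_ml"].median()),
        set_peak_pressure=float(truth["peak_pressure_cmh2o"].median()),
        set_rate=None if config.cpr_mode == "synchronous" else config.rate,
        duration=config.duration,
    )


def run_demo_dataset(
    configs: Sequence[SimulationConfig],
    params: AlgorithmParams | None = None,
) -> dict:
    """Simulate, detect and evaluate a list of runs fully in memory.

    Returns a dict with the pooled pairs frame, the per-(cpr_mode, measure)
    summary, per-run detected/truth breath counts, and the raw per-run
    results.
    """
    params = params if params is not None else AlgorithmParams()
    per_run = []
    counts = []
    for config in configs:
        recording, truth = simulate_run(config)
        events, measures = analyze_recording(recording, params)
        settings = settings_from_truth(config, truth)
        per_run.append((events, measures, settings))
        counts.append(
            {
                "run_id": config.run_id,
                "cpr_mode": config.cpr_mode,
                "detected": sum(1 for ev in events if not ev.truncated),
                "detected_incl_truncated": len(events),
                "truth": len(truth),
            }
        )
    pairs = pairs_dataframe(per_run)
    return {
        "pairs": pairs,
        "summary": summarize_by_group(pairs),
        "counts": pd.DataFrame(counts),
        "runs": per_run,
    }
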