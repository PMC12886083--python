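"""Per-breath ventilation measures over delimited active phases.

Volumes integrate the *raw* flow signal (rectangular rule, sum times sample
period) over the half-open breath interval ``[start, extended_end)`` — the
post-quiescence extension is included deliberately so the expiratory tail is
captured. Inspiratory volume sums the positive flow, expiratory volume the
magnitude of the negative flow; their relative difference approximates the
airway leak fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    AlgorithmParams,
    BreathEvent,
    ConsistencyError,
    WaveformRecording,
    seconds_to_span,
)

__all__ = [
    "BreathMeasures",
    "inspiratory_volume",
    "expiratory_volume",
    "peak_pressure",
    "breath_rates",
    "et_co2",
    "leak_fraction",
    "measure_breaths",
]


@dataclass(frozen=True)
class BreathMeasures:
    """Measures for one ventilation.

    Volumes in ml (expiratory reported as a positive magnitude), peak
    pressure in cmH2O, instantaneous rate in breaths/min (None for the first
    breath of a recording), etCO2 in the CO2 channel's units (None without a
    CO2 channel), and the leak fraction (insp - exp) / insp (None when the
    inspiratory volume is zero).
    """

    insp_volume: float
    exp_volume: float
    peak_pressure: float
    inst_rate: float | None = None
    etco2: float | None = None
    leak_fraction: float | None = None


def _event_slice(recording: WaveformRecording, event: BreathEvent) -> slice:
    if not (0 <= event.start_index < event.extended_end_index <= recording.n_samples):
        raise ConsistencyError(
            f"event [{event.start_index}, {event.extended_end_index}) outside record "
            f"of {recording.n_samples} samples"
        )
    return slice(event.start_index, event.extended_end_index)


def inspiratory_volume(recording: WaveformRecording, event: BreathEvent) -> float:
    """Sum of positive flow over the breath, in ml (L/min * s / 60 * 1000)."""
    seg = recording.flow[_event_slice(recording, event)]
    return float(np.sum(np.clip(seg, 0.0, None)) * recording.dt / 60.0 * 1000.0)


def expiratory_volume(recording: WaveformRecording, event: BreathEvent) -> float:
    """Magnitude of the summed negative flow over the breath, in ml."""
    seg = recording.flow[_event_slice(recording, event)]
    return float(-np.sum(np.clip(seg, None, 0.0)) * recording.dt / 60.0 * 1000.0)


def peak_pressure(recording: WaveformRecording, event: BreathEvent) -> float:
    """Maximum airway pressure over the breath, in cmH2O."""
    seg = recording.pressure[_event_slice(recording, event)]
    return float(seg.max())


def breath_rates(events: Sequence[BreathEvent]) -> list[float | None]:
    """Instantaneous rate per breath: 60 / preceding inter-start interval.

    The first breath has no preceding interval and reports None.
    """
    starts = [ev.start_time for ev in events]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ConsistencyError("events must be ordered by strictly increasing start time")
    rates: list[float | None] = [None] if events else []
    rates.extend(60.0 / (b - a) for a, b in zip(starts, starts[1:]))
    return rates


def leak_fraction(insp_volume: float, exp_volume: float) -> float | None:
    """(insp - exp) / insp; undefined (None) when no inspiratory volume."""
    if insp_volume > 0:
        return (insp_volume - exp_volume) / insp_volume
    return None


def et_co2(
    recording: WaveformRecording,
    event: BreathEvent,
    next_event: BreathEvent | None,
    params: AlgorithmParams,
) -> float | None:
    """Maximum CO2 attributable to a breath, or None without a CO2 channel.

    The window is ``[start + co2_delay, next_start + co2_delay)`` (record end
    standing in for the next start on the last breath), clipped to the
    record: the delay keeps the final expired CO2 from being credited to the
    subsequent ventilation.
    """
    if recording.co2 is None:
        return None
    delay = seconds_to_span(params.co2_delay, recording.sampling_rate)
    lo = event.start_index + delay
    hi = (next_event.start_index if next_event is not None else recording.n_samples) + delay
    lo = max(0, min(lo, recording.n_samples))
    hi = max(0, min(hi, recording.n_samples))
    if lo >= hi:
        return None
    return float(recording.co2[lo:hi].max())


def measure_breaths(
    recording: WaveformRecording,
    events: Sequence[BreathEvent],
    params: AlgorithmParams | None = None,
) -> list[BreathMeasures]:
    """Compute all per-breath measures for a segmented recording."""
    params = params if params is not None else AlgorithmParams()
    rates = breath_rates(events)
    out: list[BreathMeasures] = []
    for i, ev in enumerate(events):
        insp = inspiratory_volume(recording, ev)
        exp = expiratory_volume(recording, ev)
        nxt = events[i + 1] if i + 1 < len(events) else None
        out.append(
            BreathMeasures(
                insp_volume=insp,
                exp_volume=exp,
                peak_pressure=peak_pressure(recording, ev),
                inst_rate=rates[i],
                etco2=et_co2(recording, ev, nxt, params),
                leak_fraction=leak_fraction(insp, exp),
            )
        )
    return out
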