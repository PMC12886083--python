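"""Breath detection: delimit ventilations and reject chest-compression artefacts.

The detector works on pressure and flow jointly. A ventilation is *anchored*
where airway pressure crosses the threshold A upward and stays at or above A
for the sustain duration B — a condition compression artefacts (small, short
pressure oscillations) fail, while positive-pressure insufflations pass. The
insufflation is taken to begin a lead C before the anchor. The *active
phase* (insufflation plus detectable exsufflation) ends at the first instant
where both the one-second trailing average of absolute flow, corrected by a
per-breath baseline, has fallen below the threshold D, and pressure is back
below A. Because ongoing compressions keep absolute flow continually
elevated, the baseline is the minimum of the smoothed absolute flow over the
first 6 s of the breath — so the end test measures flow *above* the
compression floor. The end is finally extended by a fixed delay E to capture
the expiratory tail.

All comparisons against thresholds are strict (< D, < A); ties count as
"still active". The end-condition search may not terminate before
``start + min_duration`` (0.3 s), which prevents compression artefacts from
splitting one true ventilation into several.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    NO_INACTIVE_PHASE,
    AlgorithmParams,
    BreathEvent,
    ConsistencyError,
    WaveformRecording,
    moving_average_abs_flow,
    seconds_to_min_offset,
    seconds_to_span,
)

__all__ = [
    "DetectionTrace",
    "detect_anchor",
    "compute_flow_baseline",
    "delimit_active_phase",
    "segment_recording",
    "REJECT_TOO_SHORT",
    "REJECT_RECORD_END",
    "REJECT_REFRACTORY",
    "ACCEPTED",
]

ACCEPTED = "accepted"
#: Pressure crossed A but did not stay >= A for the full sustain duration B.
REJECT_TOO_SHORT = "too_short"
#: Pressure crossed A too close to the record end to evaluate the sustain window.
REJECT_RECORD_END = "record_end"
#: Crossing fell inside an earlier breath's [start, extended_end) interval.
REJECT_REFRACTORY = "refractory"


@dataclass
class DetectionTrace:
    """Diagnostic companion to segmentation.

    ``candidates`` lists every upward crossing of the pressure threshold with
    its fate (accepted / too_short / record_end / refractory); pulses that
    never reach the threshold produce no candidate at all.
    """

    smoothed_abs_flow: np.ndarray
    candidates: list[tuple[float, str]] = field(default_factory=list)
    events: list[BreathEvent] = field(default_factory=list)


def _crossing_indices(pressure: np.ndarray, threshold: float) -> np.ndarray:
    """Indices where pressure crosses the threshold upward (record start counts)."""
    above = pressure >= threshold
    fresh = np.concatenate(([True], ~above[:-1]))
    return np.flatnonzero(above & fresh)


def _sustained(pressure: np.ndarray, i: int, n_sustain: int, threshold: float) -> bool:
    return bool(np.all(pressure[i : i + n_sustain + 1] >= threshold))


def _detect_anchor_index(
    pressure: np.ndarray,
    sampling_rate: float,
    params: AlgorithmParams,
    search_index: int,
) -> int | None:
    """Earliest anchor index at or after ``search_index``, or None."""
    n = pressure.size
    n_sustain = seconds_to_span(params.pressure_duration_B, sampling_rate)
    for i in _crossing_indices(pressure, params.pressure_threshold_A):
        if i < search_index:
            continue
        if i + n_sustain > n - 1:
            return None  # remaining crossings are even closer to the end
        if _sustained(pressure, i, n_sustain, params.pressure_threshold_A):
            return int(i)
    return None


def detect_anchor(
    recording: WaveformRecording,
    params: AlgorithmParams,
    search_from: float = None,
) -> float | None:
    """Earliest anchor time at or after ``search_from`` (seconds), or None.

    An anchor is a fresh upward crossing of the pressure threshold A (or the
    record start with pressure already >= A) where pressure then stays >= A
    for the whole sustain window B. Absence of an anchor is a valid result.
    """
    if search_from is None:
        search_from = recording.start_time
    if not (recording.start_time <= search_from <= recording.end_time):
        raise ConsistencyError(
            f"search_from {search_from} outside record "
            f"[{recording.start_time}, {recording.end_time}]"
        )
    idx = _detect_anchor_index(
        recording.pressure, recording.sampling_rate, params, recording.index_at(search_from)
    )
    return None if idx is None else recording.time_at(idx)


def _baseline_index(
    smoothed: np.ndarray, start_index: int, params: AlgorithmParams, sampling_rate: float
) -> float:
    n = smoothed.size
    if not 0 <= start_index < n:
        raise ConsistencyError(f"baseline window start {start_index} outside record")
    hi = min(n, start_index + seconds_to_span(params.baseline_window, sampling_rate) + 1)
    return float(smoothed[start_index:hi].min())


def compute_flow_baseline(
    smoothed_abs_flow: np.ndarray,
    start: float,
    params: AlgorithmParams,
    sampling_rate: float,
    start_time: float = 0.0,
) -> float:
    """Minimum of the smoothed absolute flow over the baseline window.

    The window runs from ``start`` (seconds) for ``params.baseline_window``
    seconds, clipped at the record end. Restricting the window to the start
    of the breath keeps later compression pauses (in synchronous regimes)
    from being mistaken for the quiescent floor.
    """
    idx = seconds_to_min_offset(start - start_time, sampling_rate)
    return _baseline_index(smoothed_abs_flow, idx, params, sampling_rate)


def _delimit_index(
    recording: WaveformRecording,
    smoothed: np.ndarray,
    anchor_index: int,
    prev_end_index: int,
    params: AlgorithmParams,
) -> BreathEvent:
    n = recording.n_samples
    fs = recording.sampling_rate
    pressure = recording.pressure
    if not 0 <= anchor_index < n:
        raise ConsistencyError(f"anchor index {anchor_index} outside record")
    if prev_end_index > anchor_index:
        raise ConsistencyError("previous breath end lies after the anchor")

    start = max(prev_end_index, anchor_index - seconds_to_span(params.ventilation_lead_C, fs), 0)
    baseline = _baseline_index(smoothed, start, params, fs)

    if params.abs_flow_threshold_D == NO_INACTIVE_PHASE:
        nxt = _detect_anchor_index(pressure, fs, params, anchor_index + 1)
        active_end = nxt if nxt is not None else n
        extended_end = active_end
        truncated = False
    else:
        search0 = max(
            anchor_index + seconds_to_min_offset(params.pressure_duration_B, fs),
            start + seconds_to_min_offset(params.min_duration, fs),
        )
        active_end = None
        if search0 < n:
            quiet = (smoothed - baseline < params.abs_flow_threshold_D) & (
                pressure < params.pressure_threshold_A
            )
            rel = np.flatnonzero(quiet[search0:])
            if rel.size:
                active_end = search0 + int(rel[0])
        if active_end is None:
            active_end = n
            extended_end = n
            truncated = True
        else:
            truncated = False
            nxt = _detect_anchor_index(pressure, fs, params, active_end)
            extended_end = active_end + seconds_to_span(params.inactive_delay_E, fs)
            extended_end = min(extended_end, n, nxt if nxt is not None else n)

    return BreathEvent(
        anchor_time=recording.time_at(anchor_index),
        start_time=recording.time_at(start),
        active_end_time=recording.time_at(active_end),
        extended_end_time=recording.time_at(extended_end),
        baseline_flow=baseline,
        anchor_index=anchor_index,
        start_index=start,
        active_end_index=active_end,
        extended_end_index=extended_end,
        truncated=truncated,
    )


def delimit_active_phase(
    recording: WaveformRecording,
    anchor: float,
    prev_end: float | None = None,
    params: AlgorithmParams | None = None,
    smoothed_abs_flow: np.ndarray | None = None,
) -> BreathEvent:
    """Delimit one breath's active phase around an accepted anchor time.

    ``prev_end`` (seconds) clips the lead-extended start against the
    previous breath; it defaults to the record start.
    """
    params = params if params is not None else AlgorithmParams()
    if smoothed_abs_flow is None:
        smoothed_abs_flow = moving_average_abs_flow(recording, params.smooth_window)
    if prev_end is None:
        prev_end = recording.start_time
    anchor_index = int(round((anchor - recording.start_time) * recording.sampling_rate))
    return _delimit_index(
        recording,
        smoothed_abs_flow,
        anchor_index,
        recording.index_at(prev_end),
        params,
    )


def segment_recording(
    recording: WaveformRecording,
    params: AlgorithmParams | None = None,
) -> tuple[list[BreathEvent], DetectionTrace]:
    """Segment a recording into ordered, non-overlapping breath events.

    The anchor search restarts at each breath's extended end (refractory
    rule), so no new ventilation can begin inside a previous breath's
    interval and the E-extension can never swallow the next breath's start.
    The procedure is deterministic: identical inputs yield identical output.
    """
    params = params if params is not None else AlgorithmParams()
    smoothed = moving_average_abs_flow(recording, params.smooth_window)
    pressure = recording.pressure
    fs = recording.sampling_rate
    n = recording.n_samples

    events: list[BreathEvent] = []
    search = 0
    while search < n:
        anchor = _detect_anchor_index(pressure, fs, params, search)
        if anchor is None:
            break
        event = _delimit_index(recording, smoothed, anchor, search, params)
        events.append(event)
        if event.extended_end_index <= search:  # pragma: no cover - progress guard
            break
        search = event.extended_end_index
        if event.truncated:
            break

    # Post-hoc candidate bookkeeping for the diagnostic trace.
    n_sustain = seconds_to_span(params.pressure_duration_B, fs)
    accepted = {ev.anchor_index for ev in events}
    candidates: list[tuple[float, str]] = []
    for i in _crossing_indices(pressure, params.pressure_threshold_A):
        i = int(i)
        if i in accepted:
            status = ACCEPTED
        elif any(ev.start_index <= i < ev.extended_end_index for ev in events):
            status = REJECT_REFRACTORY
        elif i + n_sustain > n - 1:
            status = REJECT_RECORD_END
        elif not _sustained(pressure, i, n_sustain, params.pressure_threshold_A):
            status = REJECT_TOO_SHORT
        else:  # sustained crossing after a truncated trailing breath
            status = REJECT_REFRACTORY
        candidates.append((recording.time_at(i), status))

    return events, DetectionTrace(smoothed_abs_flow=smoothed, candidates=candidates, events=events)
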