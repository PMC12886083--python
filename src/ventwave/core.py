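"""Core waveform containers, file I/O, and the shared smoothing primitive.

Conventions used throughout the package
---------------------------------------
* Flow is in litres per minute (L/min); positive flow is gas moving toward
  the lung (inspiratory).
* Airway pressure is in cmH2O.
* CO2 is passed through in whatever unit the capnograph reports (mmHg or
  kPa); only maxima are taken downstream, which are unit-covariant.
* Channels are uniformly sampled; sample ``k`` corresponds to time
  ``start_time + k / sampling_rate``.
* Durations are converted to sample counts with a small epsilon guard so
  that exact multiples of the sample period land on the intended sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VentwaveError",
    "FormatError",
    "SamplingError",
    "ParameterError",
    "ConsistencyError",
    "DegenerateInputError",
    "NO_INACTIVE_PHASE",
    "WaveformRecording",
    "AlgorithmParams",
    "BreathEvent",
    "PROFILES",
    "get_profile",
    "moving_average_abs_flow",
    "read_waveform",
    "write_breath_table",
    "read_breath_table",
    "seconds_to_span",
    "seconds_to_min_offset",
    "BREATH_TABLE_COLUMNS",
]


class VentwaveError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(VentwaveError):
    """An input file does not have the expected structure."""


class SamplingError(VentwaveError):
    """Time stamps are inconsistent with the declared sampling rate."""


class ParameterError(VentwaveError):
    """An algorithm or simulation parameter is out of its valid range."""


class ConsistencyError(VentwaveError):
    """Arguments are mutually inconsistent (e.g. an event outside its record)."""


class DegenerateInputError(VentwaveError):
    """The input is too small or too uniform for the requested statistic."""


#: Sentinel for the absolute-flow threshold meaning "no inactive phase":
#: the active phase of a breath runs until the next detected breath (or the
#: record end) instead of ending at a flow/pressure quiescence condition.
NO_INACTIVE_PHASE = -1.0

_EPS = 1e-9


def seconds_to_span(seconds: float, sampling_rate: float) -> int:
    """Largest sample offset contained in a closed interval of ``seconds``.

    Used for closed-interval windows such as the sustained-pressure check:
    samples ``i .. i + seconds_to_span(B, fs)`` all lie within ``B`` seconds
    of sample ``i``.
    """
    return int(math.floor(seconds * sampling_rate + _EPS))


def seconds_to_min_offset(seconds: float, sampling_rate: float) -> int:
    """Smallest sample offset at or after ``seconds`` from a reference sample."""
    return int(math.ceil(seconds * sampling_rate - _EPS))


@dataclass(frozen=True)
class WaveformRecording:
    """A uniformly sampled multichannel ventilation recording.

    Parameters
    ----------
    flow : array-like
        Airway flow in L/min, positive toward the lung.
    pressure : array-like
        Airway pressure in cmH2O.
    sampling_rate : float
        Samples per second (the field devices sample at 256 Hz).
    co2 : array-like, optional
        Capnogram in device units; passed through unchanged.
    start_time : float
        Time of the first sample, in seconds.
    run_id : str
        Opaque label for the recording.
    """

    flow: np.ndarray
    pressure: np.ndarray
    sampling_rate: float = 256.0
    co2: np.ndarray | None = None
    start_time: float = 0.0
    run_id: str = ""

    def __post_init__(self) -> None:
        flow = np.asarray(self.flow, dtype=float)
        pressure = np.asarray(self.pressure, dtype=float)
        co2 = None if self.co2 is None else np.asarray(self.co2, dtype=float)
        if not self.sampling_rate > 0:
            raise ParameterError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if flow.ndim != 1 or pressure.ndim != 1:
            raise FormatError("flow and pressure must be one-dimensional")
        if flow.size < 1:
            raise DegenerateInputError("recording must contain at least one sample")
        if pressure.size != flow.size or (co2 is not None and co2.size != flow.size):
            raise FormatError("all channels must have identical length")
        for name, ch in (("flow", flow), ("pressure", pressure), ("co2", co2)):
            if ch is not None and not np.all(np.isfinite(ch)):
                raise FormatError(f"channel {name!r} contains missing or non-finite values")
        object.__setattr__(self, "flow", flow)
        object.__setattr__(self, "pressure", pressure)
        object.__setattr__(self, "co2", co2)

    @property
    def n_samples(self) -> int:
        return int(self.flow.size)

    @property
    def dt(self) -> float:
        """Sample period in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Record duration in seconds (number of samples times the period)."""
        return self.n_samples / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float, clip: bool = True) -> int:
        """Index of the first sample at or after time ``t``."""
        i = seconds_to_min_offset(t - self.start_time, self.sampling_rate)
        if clip:
            i = min(max(i, 0), self.n_samples)
        return i

    def time_at(self, index: int) -> float:
        return self.start_time + index / self.sampling_rate


@dataclass(frozen=True)
class AlgorithmParams:
    """Tunable thresholds of the breath detector plus its fixed constants.

    The five tunable parameters follow the detector's geometry: a breath is
    anchored where pressure sustains at least ``pressure_threshold_A`` cmH2O
    for ``pressure_duration_B`` seconds; the insufflation is taken to start
    ``ventilation_lead_C`` seconds earlier; the active phase ends once the
    baseline-corrected one-second-averaged absolute flow drops below
    ``abs_flow_threshold_D`` L/min while pressure is back below A, and is
    then extended by ``inactive_delay_E`` seconds to capture the expiratory
    tail. ``abs_flow_threshold_D == -1`` disables the inactive phase
    entirely. Defaults are the manually tuned field profile.
    """

    pressure_threshold_A: float = 8.0
    pressure_duration_B: float = 0.3
    ventilation_lead_C: float = 0.3
    abs_flow_threshold_D: float = 5.0
    inactive_delay_E: float = 0.2
    min_duration: float = 0.3
    smooth_window: float = 1.0
    baseline_window: float = 6.0
    co2_delay: float = 0.5

    def __post_init__(self) -> None:
        if not self.pressure_threshold_A > 0:
            raise ParameterError("pressure_threshold_A must be > 0")
        if self.pressure_duration_B < 0:
            raise ParameterError("pressure_duration_B must be >= 0")
        if self.ventilation_lead_C < 0:
            raise ParameterError("ventilation_lead_C must be >= 0")
        if self.inactive_delay_E < 0:
            raise ParameterError("inactive_delay_E must be >= 0")
        if not (self.abs_flow_threshold_D > 0 or self.abs_flow_threshold_D == NO_INACTIVE_PHASE):
            raise ParameterError(
                "abs_flow_threshold_D must be > 0 or the sentinel -1 (no inactive phase)"
            )
        if not self.min_duration > 0:
            raise ParameterError("min_duration must be > 0")
        if not self.smooth_window > 0:
            raise ParameterError("smooth_window must be > 0")
        if not self.baseline_window > 0:
            raise ParameterError("baseline_window must be > 0")
        if self.co2_delay < 0:
            raise ParameterError("co2_delay must be >= 0")

    @classmethod
    def tuned(cls) -> "AlgorithmParams":
        """The manually tuned profile selected after clinical review (default)."""
        return cls()

    @classmethod
    def optimized(cls) -> "AlgorithmParams":
        """The profile that minimizes the grid-search objective on bench data."""
        return cls(
            pressure_threshold_A=2.0,
            pressure_duration_B=0.3,
            ventilation_lead_C=0.1,
            abs_flow_threshold_D=1.0,
            inactive_delay_E=0.2,
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "AlgorithmParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}

    def replace(self, **kwargs: float) -> "AlgorithmParams":
        return replace(self, **kwargs)


PROFILES: dict[str, AlgorithmParams] = {
    "tuned": AlgorithmParams.tuned(),
    "optimized": AlgorithmParams.optimized(),
}


def get_profile(name: str) -> AlgorithmParams:
    """Look up a named parameter profile (``"tuned"`` or ``"optimized"``)."""
    try:
        return PROFILES[name]
    except KeyError:
        raise ParameterError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}"
        ) from None


@dataclass(frozen=True)
class BreathEvent:
    """One detected ventilation, delimited on the sample grid.

    ``anchor_time`` is the first sample of the sustained-pressure window;
    ``start_time`` precedes it by the ventilation lead (clipped against the
    previous breath); ``active_end_time`` is the first sample meeting the
    end-of-breath condition; ``extended_end_time`` adds the inactive delay
    (clipped at the record end and one sample before the next anchor).
    Index fields locate the same boundaries on the sample grid; the sample
    at ``extended_end_index`` is *excluded* from the breath (half-open
    interval).
    """

    anchor_time: float
    start_time: float
    active_end_time: float
    extended_end_time: float
    baseline_flow: float
    anchor_index: int
    start_index: int
    active_end_index: int
    extended_end_index: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.start_index <= self.anchor_index < self.active_end_index <= self.extended_end_index):
            raise ConsistencyError(
                "breath boundaries must satisfy start <= anchor < active_end <= extended_end; got "
                f"{self.start_index}, {self.anchor_index}, {self.active_end_index}, {self.extended_end_index}"
            )

    @property
    def duration(self) -> float:
        return self.extended_end_time - self.start_time


def moving_average_abs_flow(recording: WaveformRecording, window: float) -> np.ndarray:
    """Trailing moving average of ``|flow|`` over ``window`` seconds.

    At sample ``k`` the value is the mean of ``|flow|`` over the samples in
    the half-open time window ``(t_k - window, t_k]``. At the record start,
    where fewer samples are available, the partial window is averaged over
    the available samples (so a constant signal maps to a constant). The
    average is trailing (causal) so that the end-of-breath test never looks
    at future samples.
    """
    if not window > 0:
        raise ParameterError(f"window must be > 0, got {window}")
    m = max(1, int(math.ceil(window * recording.sampling_rate - _EPS)))
    af = np.abs(recording.flow)
    cs = np.concatenate(([0.0], np.cumsum(af)))
    k = np.arange(af.size)
    lo = np.maximum(0, k + 1 - m)
    return (cs[k + 1] - cs[lo]) / (k + 1 - lo)


_DEFAULT_COLUMNS = {
    "time": "time_s",
    "flow": "flow_lpm",
    "pressure": "pressure_cmh2o",
    "co2": "co2",
}

_TIME_TOLERANCE = 1e-6  # seconds; max deviation of a stamp from the uniform grid


def read_waveform(
    path: str | Path,
    sampling_rate: float = 256.0,
    column_map: Mapping[str, str] | None = None,
    run_id: str | None = None,
) -> WaveformRecording:
    """Read a waveform CSV into a validated :class:`WaveformRecording`.

    The canonical dialect is comma-separated UTF-8 with a header row and
    columns ``flow_lpm``, ``pressure_cmh2o`` and optionally ``time_s`` and
    ``co2``; ``column_map`` maps the logical names ``flow``, ``pressure``,
    ``co2``, ``time`` onto different header names. Units are taken as
    declared (L/min with positive = inspiratory, cmH2O); no rescaling is
    applied. If a time column is present it must step uniformly at the
    declared rate to within 1e-6 s.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"waveform file not found: {path}")
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"waveform file is empty: {path}") from None
    if df.empty:
        raise FormatError(f"waveform file has a header but no samples: {path}")
    for logical in ("flow", "pressure"):
        if cols[logical] not in df.columns:
            raise FormatError(
                f"waveform file {path} is missing mandatory column {cols[logical]!r}"
            )
    start_time = 0.0
    if cols["time"] in df.columns:
        t = df[cols["time"]].to_numpy(dtype=float)
        start_time = float(t[0])
        expected = start_time + np.arange(t.size) / sampling_rate
        dev = np.abs(t - expected)
        bad = np.flatnonzero(dev > _TIME_TOLERANCE)
        if bad.size:
            i = int(bad[0])
            raise SamplingError(
                f"time stamps are not uniform at {sampling_rate} Hz: first offending "
                f"index {i} (stamp {t[i]:.9f}, expected {expected[i]:.9f})"
            )
    co2 = df[cols["co2"]].to_numpy(dtype=float) if cols["co2"] in df.columns else None
    return WaveformRecording(
        flow=df[cols["flow"]].to_numpy(dtype=float),
        pressure=df[cols["pressure"]].to_numpy(dtype=float),
        sampling_rate=sampling_rate,
        co2=co2,
        start_time=start_time,
        run_id=run_id if run_id is not None else path.stem,
    )


BREATH_TABLE_COLUMNS = [
    "breath_index",
    "start_time_s",
    "anchor_time_s",
    "active_end_s",
    "extended_end_s",
    "insp_volume_ml",
    "exp_volume_ml",
    "peak_pressure_cmh2o",
    "inst_rate_per_min",
    "etco2",
    "leak_fraction",
    "truncated",
]


def write_breath_table(
    events: Sequence[BreathEvent],
    measures: Sequence["object"],
    path: str | Path,
) -> None:
    """Write one CSV row per breath (deterministic column order, >=6 sig digits).

    ``measures`` is a sequence of :class:`~ventwave.measures.BreathMeasures`
    index-aligned with ``events``.
    """
    if len(events) != len(measures):
        raise ConsistencyError(
            f"events ({len(events)}) and measures ({len(measures)}) must be index-aligned"
        )
    rows = []
    for i, (ev, m) in enumerate(zip(events, measures)):
        rows.append(
            {
                "breath_index": i,
                "start_time_s": ev.start_time,
                "anchor_time_s": ev.anchor_time,
                "active_end_s": ev.active_end_time,
                "extended_end_s": ev.extended_end_time,
                "insp_volume_ml": m.insp_volume,
                "exp_volume_ml": m.exp_volume,
                "peak_pressure_cmh2o": m.peak_pressure,
                "inst_rate_per_min": np.nan if m.inst_rate is None else m.inst_rate,
                "etco2": np.nan if m.etco2 is None else m.etco2,
                "leak_fraction": np.nan if m.leak_fraction is None else m.leak_fraction,
                "truncated": bool(ev.truncated),
            }
        )
    df = pd.DataFrame(rows, columns=BREATH_TABLE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def read_breath_table(path: str | Path) -> pd.DataFrame:
    """Read a breath table written by :func:`write_breath_table`."""
    df = pd.read_csv(path)
    missing = [c for c in BREATH_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"breath table {path} is missing columns {missing}")
    return df
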