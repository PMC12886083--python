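"""Grid-search calibration of the detector thresholds against ventilator settings.

Each bench run has known ventilator-set (or ventilator-measured) values for
inspiratory/expiratory volume, peak pressure and — for continuously delivered
modes — the ventilation rate. The tuning objective pairs every detected
breath's measures with the run's set values, takes the mean absolute
deviation per measure, standardizes each by the standard deviation of that
measure's *set* values across runs (so all measures weigh equally and the
denominator cannot depend on the parameter vector being evaluated), and
averages the standardized deviations. An exhaustive grid search over the
five thresholds minimizes this objective.

Breaths the detector misses relative to the expected count
(``round(set_rate * duration / 60)``) enter as zero-measurement pairs, so a
detector that finds one perfect breath per run cannot win; this miss penalty
can be switched off.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    AlgorithmParams,
    BreathEvent,
    DegenerateInputError,
    ParameterError,
    WaveformRecording,
)
from .detect import segment_recording
from .measures import BreathMeasures, measure_breaths

__all__ = [
    "MEASURE_NAMES",
    "MeasurePair",
    "RunSettings",
    "GridSpec",
    "GridResult",
    "match_breaths",
    "set_value_sd",
    "standardized_objective",
    "grid_search",
]

MEASURE_NAMES = ("insp_volume", "exp_volume", "peak_pressure", "rate")

_GRID_PARAM_FIELDS = {
    "pressure_threshold_A": "A",
    "pressure_duration_B": "B",
    "ventilation_lead_C": "C",
    "abs_flow_threshold_D": "D",
    "inactive_delay_E": "E",
}


class MeasurePair(NamedTuple):
    """One (algorithm measurement, reference value) pair for one measure."""

    measure: str
    measured: float
    set_value: float
    run_id: str = ""


@dataclass(frozen=True)
class RunSettings:
    """Reference values and metadata for one bench run.

    ``set_rate`` is absent for synchronous (30:2) runs, where breaths are
    started manually and no rate setting exists to compare with.
    ``exclude_exp`` marks runs whose ventilator expiratory measurements were
    unreliable and must not enter expiratory-volume comparisons.
    """

    run_id: str
    mode: str = "volume"
    cpr_mode: str = "none"
    set_insp_volume: float | None = None
    set_exp_volume: float | None = None
    set_peak_pressure: float | None = None
    set_rate: float | None = None
    duration: float = 120.0
    exclude_exp: bool = False

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ParameterError("duration must be > 0")
        if all(
            v is None
            for v in (
                self.set_insp_volume,
                self.set_exp_volume,
                self.set_peak_pressure,
                self.set_rate,
            )
        ):
            raise ParameterError(f"run {self.run_id!r} has no set value to compare with")

    @classmethod
    def from_mapping(cls, row: Mapping[str, object]) -> "RunSettings":
        def opt(key: str) -> float | None:
            v = row.get(key)
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            return float(v)  # type: ignore[arg-type]

        return cls(
            run_id=str(row["run_id"]),
            mode=str(row.get("mode", "volume")),
            cpr_mode=str(row.get("cpr_mode", "none")),
            set_insp_volume=opt("set_insp_volume"),
            set_exp_volume=opt("set_exp_volume"),
            set_peak_pressure=opt("set_peak_pressure"),
            set_rate=opt("set_rate"),
            duration=float(row.get("duration", 120.0) or 120.0),
            exclude_exp=bool(row.get("exclude_exp", False)),
        )


#: Default candidate values for each tunable threshold.
_DEFAULT_GRID = {
    "pressure_threshold_A": (1.0, 2.0, 5.0, 8.0, 10.0),
    "pressure_duration_B": (0.1, 0.2, 0.3, 0.4, 0.5),
    "ventilation_lead_C": (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    "abs_flow_threshold_D": (-1.0, 1.0, 5.0, 10.0),
    "inactive_delay_E": (0.0, 0.1, 0.2, 0.3),
}


@dataclass(frozen=True)
class GridSpec:
    """Candidate value lists for the five tunable thresholds."""

    pressure_threshold_A: tuple[float, ...] = _DEFAULT_GRID["pressure_threshold_A"]
    pressure_duration_B: tuple[float, ...] = _DEFAULT_GRID["pressure_duration_B"]
    ventilation_lead_C: tuple[float, ...] = _DEFAULT_GRID["ventilation_lead_C"]
    abs_flow_threshold_D: tuple[float, ...] = _DEFAULT_GRID["abs_flow_threshold_D"]
    inactive_delay_E: tuple[float, ...] = _DEFAULT_GRID["inactive_delay_E"]

    def __post_init__(self) -> None:
        for name in _GRID_PARAM_FIELDS:
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ParameterError(f"grid for {name} must be non-empty")
            object.__setattr__(self, name, vals)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[float]]) -> "GridSpec":
        unknown = set(mapping) - set(_GRID_PARAM_FIELDS)
        if unknown:
            raise ParameterError(f"unknown grid keys: {sorted(unknown)}")
        return cls(**{k: tuple(float(x) for x in v) for k, v in mapping.items()})

    @property
    def n_points(self) -> int:
        return int(np.prod([len(getattr(self, k)) for k in _GRID_PARAM_FIELDS]))

    def points(self) -> Iterable[dict[str, float]]:
        """All parameter combinations, in ascending lexicographic (A,B,C,D,E) order."""
        names = list(_GRID_PARAM_FIELDS)
        for combo in itertools.product(*(sorted(getattr(self, k)) for k in names)):
            yield dict(zip(names, combo))


@dataclass
class GridResult:
    """Full evaluation table and the winning parameter vector."""

    table: pd.DataFrame
    best: AlgorithmParams
    best_objective: float


def match_breaths(
    events: Sequence[BreathEvent],
    measures: Sequence[BreathMeasures],
    settings: RunSettings,
    include_missed: bool = True,
) -> list[MeasurePair]:
    """Pair each detected breath's measures with the run's reference values.

    Truncated trailing breaths are excluded. When the run has a set rate and
    ``include_missed`` is on, breaths missing relative to the expected count
    contribute zero-measurement pairs for every volume/pressure measure.
    """
    pairs: list[MeasurePair] = []
    kept = [
        (ev, m) for ev, m in zip(events, measures) if not ev.truncated
    ]
    refs = [
        ("insp_volume", settings.set_insp_volume, lambda m: m.insp_volume),
        (
            "exp_volume",
            None if settings.exclude_exp else settings.set_exp_volume,
            lambda m: m.exp_volume,
        ),
        ("peak_pressure", settings.set_peak_pressure, lambda m: m.peak_pressure),
    ]
    for ev, m in kept:
        for name, set_value, get in refs:
            if set_value is not None:
                pairs.append(MeasurePair(name, get(m), set_value, settings.run_id))
        if settings.set_rate is not None and m.inst_rate is not None:
            pairs.append(MeasurePair("rate", m.inst_rate, settings.set_rate, settings.run_id))
    if include_missed and settings.set_rate is not None:
        expected = int(round(settings.set_rate * settings.duration / 60.0))
        for _ in range(max(0, expected - len(kept))):
            for name, set_value, _get in refs:
                if set_value is not None:
                    pairs.append(MeasurePair(name, 0.0, set_value, settings.run_id))
    return pairs


def set_value_sd(settings: Sequence[RunSettings]) -> dict[str, float]:
    """Sample SD of each measure's set values across runs (NaN when undefined)."""
    per_measure = {
        "insp_volume": [s.set_insp_volume for s in settings],
        "exp_volume": [s.set_exp_volume for s in settings if not s.exclude_exp],
        "peak_pressure": [s.set_peak_pressure for s in settings],
        "rate": [s.set_rate for s in settings],
    }
    out: dict[str, float] = {}
    for name, values in per_measure.items():
        vals = np.array([v for v in values if v is not None], dtype=float)
        out[name] = float(np.std(vals, ddof=1)) if vals.size >= 2 else float("nan")
    return out


def standardized_objective(
    pairs: Sequence[MeasurePair],
    settings: Sequence[RunSettings],
    per_run: bool = False,
) -> tuple[float, dict[str, float]]:
    """Average standardized absolute deviation over the available measures.

    For each measure the mean absolute deviation of its pairs (pooled over
    breaths by default; per run first with ``per_run``) is divided by the
    across-run SD of its set values; the objective is the unweighted mean
    over measures with a defined, positive SD. Measures without one are
    excluded with a warning. Returns ``(objective, per-measure deviations)``.
    """
    if not pairs:
        raise DegenerateInputError("no pairs to evaluate")
    sds = set_value_sd(settings)
    devs: dict[str, float] = {}
    for name in MEASURE_NAMES:
        sub = [p for p in pairs if p.measure == name]
        if not sub:
            continue
        sd = sds.get(name, float("nan"))
        if not sd > 0 or math.isnan(sd):
            warnings.warn(
                f"measure {name!r} excluded from objective: set-value SD across runs "
                "is zero or undefined",
                stacklevel=2,
            )
            continue
        if per_run:
            by_run: dict[str, list[float]] = {}
            for p in sub:
                by_run.setdefault(p.run_id, []).append(abs(p.measured - p.set_value))
            mad = float(np.mean([np.mean(v) for v in by_run.values()]))
        else:
            mad = float(np.mean([abs(p.measured - p.set_value) for p in sub]))
        devs[name] = mad / sd
    if not devs:
        raise DegenerateInputError("no measure with a usable set-value SD")
    return float(np.mean(list(devs.values()))), devs


def _evaluate_point(
    dataset: Sequence[tuple[WaveformRecording, RunSettings]],
    params: AlgorithmParams,
    include_missed: bool,
    per_run: bool,
) -> tuple[float, dict[str, float]]:
    pairs: list[MeasurePair] = []
    for recording, settings in dataset:
        events, _ = segment_recording(recording, params)
        measures = measure_breaths(recording, events, params)
        pairs.extend(match_breaths(events, measures, settings, include_missed))
    try:
        return standardized_objective(pairs, [s for _, s in dataset], per_run)
    except DegenerateInputError:
        return float("inf"), {}


def grid_search(
    dataset: Sequence[tuple[WaveformRecording, RunSettings]],
    grid: GridSpec | None = None,
    base_params: AlgorithmParams | None = None,
    include_missed: bool = True,
    per_run: bool = False,
) -> GridResult:
    """Exhaustively evaluate every grid point and return the argmin.

    ``base_params`` supplies the fixed constants (minimum duration, smoothing
    and baseline windows, CO2 delay). Ties in the objective break toward the
    smallest A, then B, C, D, E. Deterministic; one table row per grid point.
    """
    if not dataset:
        raise ParameterError("dataset must be non-empty")
    grid = grid if grid is not None else GridSpec()
    base = base_params if base_params is not None else AlgorithmParams()

    rows = []
    for point in grid.points():
        params = base.replace(**point)
        objective, devs = _evaluate_point(dataset, params, include_missed, per_run)
        row = {short: point[name] for name, short in _GRID_PARAM_FIELDS.items()}
        row["objective"] = objective
        for m in MEASURE_NAMES:
            row[f"dev_{m}"] = devs.get(m, float("nan"))
        rows.append(row)
    table = pd.DataFrame(rows)

    order = table.sort_values(
        ["objective", "A", "B", "C", "D", "E"], kind="mergesort"
    ).index
    best_row = table.loc[order[0]]
    best = base.replace(
        **{name: float(best_row[short]) for name, short in _GRID_PARAM_FIELDS.items()}
    )
    return GridResult(table=table, best=best, best_objective=float(best_row["objective"]))
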