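"""Agreement statistics between algorithm measures and ventilator references.

Differences are reported as median and quartiles (linear-interpolation
quartile convention, stated so results are bit-reproducible), together with
the Bland–Altman percentage error (per-pair difference divided by the pair
average, times 100; the median of these is reported), Lin's concordance
correlation coefficient, the root-mean-square error, and the proportion of
ventilations within 10 % error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DegenerateInputError, ParameterError
from .tuning import MeasurePair

__all__ = [
    "ErrorSummary",
    "error_summary",
    "percent_error",
    "lin_ccc",
    "rmse_and_within10",
    "summarize_pairs",
    "summarize_by_group",
    "plot_error_histograms",
]


@dataclass(frozen=True)
class ErrorSummary:
    """Agreement summary for one measure (one table row)."""

    measure: str
    n: int
    set_median: float
    measured_median: float
    diff_median: float
    diff_q1: float
    diff_q3: float
    percent_error: float
    ccc: float
    rmse: float
    prop_within_10pct: float


def _as_arrays(pairs: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) == 0:
        raise DegenerateInputError("at least one (measured, set) pair is required")
    arr = np.asarray(pairs, dtype=float)
    return arr[:, 0], arr[:, 1]


def error_summary(pairs: Sequence[tuple[float, float]]) -> dict[str, float]:
    """Median/IQR block of the differences ``measured - set``.

    Quartiles use linear interpolation (numpy's default percentile method).
    """
    measured, set_values = _as_arrays(pairs)
    d = measured - set_values
    q1, q2, q3 = np.percentile(d, [25.0, 50.0, 75.0])
    return {
        "n": int(d.size),
        "set_median": float(np.median(set_values)),
        "measured_median": float(np.median(measured)),
        "diff_median": float(q2),
        "diff_q1": float(q1),
        "diff_q3": float(q3),
    }


def _pair_percentages(measured: np.ndarray, set_values: np.ndarray) -> np.ndarray:
    """Bland–Altman percentage per pair; pairs with zero midpoint yield NaN."""
    mid = (measured + set_values) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mid != 0, 100.0 * (measured - set_values) / mid, np.nan)


def percent_error(pairs: Sequence[tuple[float, float]]) -> float:
    """Median Bland–Altman percentage error over the pairs."""
    measured, set_values = _as_arrays(pairs)
    p = _pair_percentages(measured, set_values)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise DegenerateInputError("all pair midpoints are zero; percentage error undefined")
    return float(np.median(p))


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2) with population (1/n)
    moments; penalizes both scatter and location/scale shift from identity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 2:
        raise ParameterError("lin_ccc requires at least 2 observations")
    sx = np.var(x)
    sy = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    denom = sx + sy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        warnings.warn("lin_ccc undefined for two constant, identical inputs", stacklevel=2)
        return float("nan")
    return float(2.0 * sxy / denom)


def rmse_and_within10(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Root-mean-square error and the proportion of pairs within 10 % error.

    A pair with zero midpoint counts as within 10 % only if its difference is
    exactly zero.
    """
    measured, set_values = _as_arrays(pairs)
    d = measured - set_values
    rmse = float(np.sqrt(np.mean(d**2)))
    p = _pair_percentages(measured, set_values)
    within = np.where(np.isnan(p), d == 0, np.abs(p) < 10.0)
    return rmse, float(np.mean(within))


def summarize_pairs(
    pairs: Sequence[tuple[float, float]], measure: str = ""
) -> ErrorSummary:
    """All agreement statistics for one measure's pairs."""
    measured, set_values = _as_arrays(pairs)
    block = error_summary(pairs)
    try:
        pct = percent_error(pairs)
    except DegenerateInputError:
        pct = float("nan")
    ccc = lin_ccc(measured, set_values) if measured.size >= 2 else float("nan")
    rmse, within = rmse_and_within10(pairs)
    return ErrorSummary(
        measure=measure,
        percent_error=pct,
        ccc=ccc,
        rmse=rmse,
        prop_within_10pct=within,
        **block,
    )


def summarize_by_group(pairs: pd.DataFrame) -> pd.DataFrame:
    """Summary table with one row per (cpr_mode, measure).

    ``pairs`` needs columns ``cpr_mode``, ``measure``, ``measured``,
    ``set_value`` (see :func:`ventwave.pipeline.pairs_dataframe`).
    """
    required = {"cpr_mode", "measure", "measured", "set_value"}
    missing = required - set(pairs.columns)
    if missing:
        raise ParameterError(f"pairs frame is missing columns {sorted(missing)}")
    rows = []
    for (cpr_mode, measure), grp in pairs.groupby(["cpr_mode", "measure"], sort=True):
        summary = summarize_pairs(
            list(zip(grp["measured"], grp["set_value"])), measure=measure
        )
        rows.append({"cpr_mode": cpr_mode, **asdict(summary)})
    return pd.DataFrame(rows)


def plot_error_histograms(pairs: pd.DataFrame, out_dir) -> list:
    """Write one error histogram PNG per (cpr_mode, measure); returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (cpr_mode, measure), grp in pairs.groupby(["cpr_mode", "measure"], sort=True):
        d = grp["measured"] - grp["set_value"]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(d, bins=30, color="tab:blue")
        ax.axvline(0.0, color="black", lw=1)
        ax.set_xlabel(f"{measure}: measured - set")
        ax.set_ylabel("count")
        ax.set_title(f"{cpr_mode}")
        fig.tight_layout()
        path = out_dir / f"errors_{cpr_mode}_{measure}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
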