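"""Cold-day counting from soil-logger series under warming scenarios.

Physiological dormancy of cold-requiring mountain seeds is released during
the weeks the soil sits near 0 degC under snow. This module reduces a soil
logger series to daily means, counts the days per annual window whose mean
is at or below the dormancy-release threshold (1 +/- 1 degC, operationalised
as daily mean <= 2.0 degC), and repeats the count after adding the scalar
temperature increments of the IPCC Representative Concentration Pathways
(RCP2.6/4.5/6.0/8.5, each with an optimistic and a less optimistic
projection). The mean count across windows is classified against the
stratification requirement: >= 60 cold days releases dormancy fully,
30-60 only partially, < 30 is insufficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Daily-mean threshold (degC): upper bound of the 1 +/- 1 degC release band.
DEFAULT_THRESHOLD = 2.0

#: Mean cold days needed for full / partial dormancy release.
FULL_RELEASE_DAYS = 60.0
PARTIAL_RELEASE_DAYS = 30.0


class ClimateDataError(ValueError):
    """Raised for malformed logger series or unusable windows."""


@dataclass(frozen=True)
class SoilTempSeries:
    """Time-ordered soil-logger readings for one site."""

    site: str
    timestamps: pd.DatetimeIndex
    temperatures: np.ndarray

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        temp = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "temperatures", temp)
        if len(ts) != len(temp):
            raise ClimateDataError("timestamps and temperatures differ in length")
        if len(ts) == 0:
            raise ClimateDataError("empty series")
        if not ts.is_monotonic_increasing or ts.has_duplicates:
            raise ClimateDataError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(temp)):
            raise ClimateDataError("non-finite temperature reading")

    def shifted(self, delta_t: float) -> "SoilTempSeries":
        return SoilTempSeries(self.site, self.timestamps, self.temperatures + delta_t)

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.timestamps[0], self.timestamps[-1]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named scalar warming increment (degC)."""

    name: str
    delta_t: float

    def __post_init__(self) -> None:
        if self.delta_t < 0:
            raise ClimateDataError(f"scenario {self.name}: delta_t must be >= 0")


#: The four RCPs, each with optimistic (OP) and less optimistic (LOP) increments.
DEFAULT_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("RCP2.6-OP", 0.3),
    ScenarioSpec("RCP2.6-LOP", 1.7),
    ScenarioSpec("RCP4.5-OP", 1.1),
    ScenarioSpec("RCP4.5-LOP", 2.6),
    ScenarioSpec("RCP6.0-OP", 1.4),
    ScenarioSpec("RCP6.0-LOP", 3.1),
    ScenarioSpec("RCP8.5-OP", 2.6),
    ScenarioSpec("RCP8.5-LOP", 4.8),
)


@dataclass(frozen=True)
class ColdDaysResult:
    """Cold-day counts per annual window under one scenario."""

    site: str
    scenario: str
    delta_t: float
    window_counts: tuple[int, ...]
    mean: float
    sd: float
    outcome: str


# ---------------------------------------------------------------------------
# Logger CSV I/O (ISO-8601 or DD/MM/YYYY HH:MM, dialect auto-detected)
# ---------------------------------------------------------------------------

def write_logger_csv(series: SoilTempSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
         "temperature_c": series.temperatures}
    ).to_csv(path, index=False)


def read_logger_csv(path: str | Path, site: str | None = None) -> SoilTempSeries:
    """Read a logger CSV (columns: timestamp, temperature_c; header required)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    ts_col = next((cols[k] for k in ("timestamp", "datetime", "date") if k in cols), None)
    temp_col = next(
        (cols[k] for k in ("temperature_c", "temperature", "temp_c", "temp") if k in cols),
        None,
    )
    if ts_col is None or temp_col is None:
        raise ClimateDataError(f"{path}: need timestamp and temperature columns")
    first = str(df[ts_col].iloc[0])
    dayfirst = "/" in first  # DD/MM/YYYY HH:MM dialect
    ts = pd.to_datetime(df[ts_col], dayfirst=dayfirst, format="mixed")
    logger.info("%s: parsed timestamps as %s", path, "DD/MM/YYYY" if dayfirst else "ISO-8601")
    return SoilTempSeries(
        site=site or "?", timestamps=pd.DatetimeIndex(ts), temperatures=df[temp_col].to_numpy(float)
    )


# ---------------------------------------------------------------------------
# Daily means and cold-day counts
# ---------------------------------------------------------------------------

def daily_means(series: SoilTempSeries) -> pd.DataFrame:
    """Arithmetic mean of all readings per calendar date.

    Returns a frame with columns date (datetime64 at midnight), mean_c,
    n_readings. Dates without readings are simply absent.
    """
    s = pd.Series(series.temperatures, index=series.timestamps)
    grouped = s.groupby(s.index.normalize())
    out = pd.DataFrame(
        {"date": grouped.mean().index, "mean_c": grouped.mean().to_numpy(),
         "n_readings": grouped.size().to_numpy()}
    ).reset_index(drop=True)
    return out


def annual_windows(
    series: SoilTempSeries, month: int = 8, day: int = 1
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Consecutive 1-year windows (default 01 Aug - 31 Jul) covering the span.

    Windows are [start, start + 1 year); only windows fully inside the series
    span are returned.
    """
    first, last = series.span
    start = pd.Timestamp(year=first.year, month=month, day=day)
    if start < first.normalize():
        start += pd.DateOffset(years=1)
    windows = []
    while start + pd.DateOffset(years=1) <= last + pd.Timedelta(days=1):
        windows.append((start, start + pd.DateOffset(years=1) - pd.Timedelta(days=1)))
        start += pd.DateOffset(years=1)
    return windows


def count_cold_days(
    daily: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    windows: Sequence[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
) -> tuple[list[int], float, float]:
    """Days per window with daily mean <= ``threshold``; plus mean +/- SD.

    Windows are inclusive [start, end] date ranges and must intersect the
    daily series; a window with no overlapping dates raises. Missing dates
    inside a window are logged, not imputed.
    """
    if daily.empty:
        raise ClimateDataError("empty daily series")
    dates = pd.DatetimeIndex(daily["date"])
    if windows is None:
        windows = [(dates[0], dates[-1])]
    counts: list[int] = []
    for start, end in windows:
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        mask = (dates >= start) & (dates <= end)
        n_present = int(mask.sum())
        if n_present == 0:
            raise ClimateDataError(f"window {start.date()}..{end.date()} outside series")
        expected = (end - start).days + 1
        if n_present < expected:
            logger.warning(
                "window %s..%s: %d of %d days present",
                start.date(), end.date(), n_present, expected,
            )
        counts.append(int((daily.loc[mask.tolist(), "mean_c"] <= threshold).sum()))
    arr = np.asarray(counts, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return counts, float(arr.mean()), sd


def classify_outcome(
    mean_cold_days: float,
    full: float = FULL_RELEASE_DAYS,
    partial: float = PARTIAL_RELEASE_DAYS,
) -> str:
    """Dormancy-release feasibility class for a mean cold-day count."""
    if mean_cold_days < 0:
        raise ClimateDataError("mean_cold_days must be >= 0")
    if mean_cold_days >= full:
        return "full_release"
    if mean_cold_days >= partial:
        return "partial_release"
    return "insufficient"


def apply_scenarios(
    series: SoilTempSeries,
    scenarios: Sequence[ScenarioSpec] = DEFAULT_SCENARIOS,
    threshold: float = DEFAULT_THRESHOLD,
    windows: Sequence[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
    include_current: bool = True,
) -> list[ColdDaysResult]:
    """Cold-day table under each warming increment (plus the current climate).

    The increment is added to every raw reading before daily averaging
    (equivalent to shifting the daily means, since the shift is additive).
    """
    if windows is None:
        windows = annual_windows(series)
    todo = list(scenarios)
    if include_current:
        todo = [ScenarioSpec("Current", 0.0)] + todo
    results = []
    for sc in todo:
        daily = daily_means(series.shifted(sc.delta_t))
        counts, mean, sd = count_cold_days(daily, threshold=threshold, windows=windows)
        results.append(
            ColdDaysResult(
                site=series.site,
                scenario=sc.name,
                delta_t=sc.delta_t,
                window_counts=tuple(counts),
                mean=mean,
                sd=sd,
                outcome=classify_outcome(mean),
            )
        )
    return results


def results_table(results: Sequence[ColdDaysResult]) -> pd.DataFrame:
    """Report-shaped frame: scenario, delta_T, per-window counts, mean, sd, outcome."""
    return pd.DataFrame(
        [
            {
                "site": r.site,
                "scenario": r.scenario,
                "delta_t": r.delta_t,
                "window_counts": ";".join(map(str, r.window_counts)),
                "mean_days": round(r.mean, 2),
                "sd_days": round(r.sd, 2) if np.isfinite(r.sd) else r.sd,
                "outcome": r.outcome,
            }
            for r in results
        ]
    )
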