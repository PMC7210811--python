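"""Synthetic germination experiments and soil-temperature logger series.

The germination generator follows the thermal-time view of seed-lot
behaviour: each viable, non-dormant seed carries a degree-day requirement
``theta`` (lognormal across the lot, median ``theta50_true``) and at a
sub-optimal incubation temperature ``T`` germinates after
``theta / (T - T_b_true)`` days. Cold stratification releases physiological
dormancy following a logistic in stratification duration. Above the optimal
plateau the germinable fraction declines linearly to zero at the ceiling
temperature while the rate stays frozen at its plateau value; at or below
the base temperature, and at or above the ceiling, nothing germinates.
Germination events are recorded on a discrete scoring schedule (first
scoring day at or after the event), exactly as a technician would score
radicle emergence.

The soil generator emulates a mountain soil logger buried a few cm deep:
annual + diurnal sinusoids, AR(1) noise, and a snowpack clamp that pins
sub-freezing excursions into a near-0 degC plateau for as long as the
seasonal cycle stays below the clamp floor.

Defaults for both generators are calibrated to the published seed-lot
behaviour of Gentiana lutea from the Gennargentu massif (two sites, 0-90 d
stratification at 1 +/- 1 degC, incubation at 5-30 degC) and to its soil
logger series; see docs/methods.md for the calibration reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .climate_projection import SoilTempSeries
from .germination_data import GerminationRecord


class InvalidParams(ValueError):
    """A simulation parameter violates its invariant."""


def default_schedule(span_days: float = 98.0) -> tuple[float, ...]:
    """Thrice-weekly scoring schedule: days 2, 4, 7 then +7 each week."""
    days: list[float] = []
    base = 0.0
    while True:
        for off in (2.0, 4.0, 7.0):
            d = base + off
            if d > span_days:
                return tuple(days)
            days.append(d)
        base += 7.0


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of the germination generator.

    Units: temperatures degC, thermal time degC d, durations days.
    ``sigma_theta`` is the SD of log thermal time across seeds (0 = a
    perfectly uniform seed lot). ``strat_half``/``strat_slope`` set the
    logistic dormancy-release curve: released fraction =
    logistic((s - strat_half) / strat_slope) after s days of cold.
    """

    T_b_true: float = 0.0
    theta50_true: float = 120.0
    sigma_theta: float = 0.15
    T_opt_hi: float = 20.0
    T_ceiling: float = 27.0
    strat_half: float = 55.0
    strat_slope: float = 12.0
    p_empty: float = 0.10
    schedule: tuple[float, ...] = field(default_factory=default_schedule)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", tuple(float(d) for d in self.schedule))
        if not self.T_b_true < self.T_opt_hi < self.T_ceiling:
            raise InvalidParams(
                "requires T_b_true < T_opt_hi < T_ceiling, got "
                f"{self.T_b_true}, {self.T_opt_hi}, {self.T_ceiling}"
            )
        if self.theta50_true <= 0:
            raise InvalidParams("theta50_true must be > 0")
        if self.sigma_theta < 0:
            raise InvalidParams("sigma_theta must be >= 0")
        if not 0 <= self.p_empty < 1:
            raise InvalidParams("p_empty must be in [0, 1)")
        if self.strat_slope <= 0:
            raise InvalidParams("strat_slope must be > 0")
        sched = np.asarray(self.schedule)
        if sched.size == 0 or np.any(np.diff(sched) <= 0):
            raise InvalidParams("schedule must be non-empty and strictly increasing")

    def release_fraction(self, strat_days: float) -> float:
        """Expected dormancy-released fraction after ``strat_days`` of cold."""
        return float(expit((strat_days - self.strat_half) / self.strat_slope))

    def germinable_fraction(self, temperature: float) -> float:
        """Fraction of released seeds able to germinate at ``temperature``.

        1 on (T_b, T_opt_hi], linear decline to 0 at T_ceiling, 0 outside.
        """
        if temperature <= self.T_b_true or temperature >= self.T_ceiling:
            return 0.0
        if temperature <= self.T_opt_hi:
            return 1.0
        return (self.T_ceiling - temperature) / (self.T_ceiling - self.T_opt_hi)

    def rate_denominator(self, temperature: float) -> float:
        """Effective (T - T_b) driving the germination rate; frozen above T_opt_hi."""
        if temperature <= self.T_b_true:
            return 0.0
        return min(temperature, self.T_opt_hi) - self.T_b_true


@dataclass(frozen=True)
class DishSpec:
    """One Petri dish in the factorial design."""

    site: str
    pretreatment_days: int
    temperature_c: float
    dish: str
    n_seeds: int = 25


def make_paper_design(n_dishes: int = 4, n_seeds: int = 25) -> list[DishSpec]:
    """The full factorial germination design used throughout this package.

    2 sites (IS, TM) x 5 stratification durations (0/15/30/60/90 d)
    x 6 incubation temperatures (5-30 degC) x 4 dishes x 25 seeds.
    """
    design = []
    for site in ("IS", "TM"):
        for pre in (0, 15, 30, 60, 90):
            for temp in (5.0, 10.0, 15.0, 20.0, 25.0, 30.0):
                for d in range(1, n_dishes + 1):
                    design.append(DishSpec(site, pre, temp, f"D{d}", n_seeds))
    return design


def _dish_rng(root_seed: int, index: int) -> np.random.Generator:
    """Deterministic per-dish substream, independent of design ordering quirks."""
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(index,)))


def dish_events(
    spec: DishSpec, params: SimulationParams, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Per-seed germination event times for one dish.

    Returns (event times in days for seeds that germinate within the schedule
    span, number of empty seeds). Seeds that stay dormant, are incapable at
    this temperature, or would germinate after the last scoring day remain
    viable-ungerminated. Draw order (empty, dormancy, capability, theta) is
    fixed so that seed fates are reproducible bit-for-bit.
    """
    n = spec.n_seeds
    empty = rng.random(n) < params.p_empty
    released = rng.random(n) < params.release_fraction(spec.pretreatment_days)
    capable = rng.random(n) < params.germinable_fraction(spec.temperature_c)
    theta = params.theta50_true * np.exp(params.sigma_theta * rng.standard_normal(n))
    denom = params.rate_denominator(spec.temperature_c)
    frac_ok = params.germinable_fraction(spec.temperature_c) > 0
    if denom > 0 and frac_ok:
        t_star = theta / denom
    else:
        t_star = np.full(n, np.inf)
    last_day = params.schedule[-1]
    germinates = (~empty) & released & capable & (t_star <= last_day)
    return t_star[germinates], int(empty.sum())


def bin_events(
    events: np.ndarray, schedule: Sequence[float]
) -> np.ndarray:
    """Cumulative germinated count at each scoring day.

    Each event is recorded at the first scoring day >= its true time.
    """
    sched = np.asarray(schedule, dtype=float)
    idx = np.searchsorted(sched, events, side="left")
    counts = np.bincount(idx, minlength=sched.size)[: sched.size]
    return np.cumsum(counts)


def simulate_germination_experiment(
    design: Iterable[DishSpec], params: SimulationParams
) -> list[GerminationRecord]:
    """Simulate every dish of ``design`` onto the scoring schedule.

    Deterministic for a given (design order, params.rng_seed): dish i uses
    substream i of the root seed.
    """
    design = list(design)
    if not design:
        raise InvalidParams("design is empty")
    records = []
    for i, spec in enumerate(design):
        rng = _dish_rng(params.rng_seed, i)
        events, n_empty = dish_events(spec, params, rng)
        cum = bin_events(events, params.schedule)
        final = int(cum[-1]) if cum.size else 0
        records.append(
            GerminationRecord(
                site=spec.site,
                pretreatment_days=spec.pretreatment_days,
                temperature_c=spec.temperature_c,
                dish=spec.dish,
                observations=tuple(zip(params.schedule, cum.tolist())),
                sown=spec.n_seeds,
                empty=n_empty,
                viable_ungerminated=spec.n_seeds - n_empty - final,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Soil-temperature logger series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TempSeriesParams:
    """Parameters of the synthetic soil-logger series (degC, days).

    The annual sinusoid peaks in mid-July and bottoms in mid-January; the
    diurnal sinusoid peaks mid-afternoon (soil at ~3 cm damps the daily
    cycle, so the default amplitude is small). Noise is AR(1) with
    stationary SD ``noise_sd``. Any raw reading below ``snow_clamp_low`` is
    replaced by a uniform draw from the clamp band - the insulating snowpack
    that pins winter soil near 0 degC.
    """

    annual_mean: float = 9.5
    annual_amplitude: float = 9.5
    diurnal_amplitude: float = 1.5
    noise_sd: float = 1.5
    noise_autocorr: float = 0.7
    snow_clamp_low: float = -0.5
    snow_clamp_high: float = 1.5
    readings_per_day: int = 4
    n_years: int = 3
    start_date: str = "2013-08-01"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise InvalidParams("n_years must be >= 1")
        if self.readings_per_day < 1:
            raise InvalidParams("readings_per_day must be >= 1")
        if not self.snow_clamp_low < self.snow_clamp_high:
            raise InvalidParams("requires snow_clamp_low < snow_clamp_high")
        if not 0 <= self.noise_autocorr < 1:
            raise InvalidParams("noise_autocorr must be in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidParams("noise_sd must be >= 0")


def mountain_preset(**overrides) -> TempSeriesParams:
    """Default Mediterranean-mountain soil preset (~1,300-1,500 m a.s.l.)."""
    return replace(TempSeriesParams(), **overrides) if overrides else TempSeriesParams()


_ANNUAL_PEAK_DOY = 197  # mid-July soil maximum
_DIURNAL_PEAK_HOUR = 15.0


def simulate_soil_temperature(params: TempSeriesParams, site: str = "IS") -> SoilTempSeries:
    """Generate a logger series of ``n_years`` whole years from ``start_date``."""
    start = pd.Timestamp(params.start_date)
    end = start + pd.DateOffset(years=params.n_years)
    n_days = (end - start).days
    n = n_days * params.readings_per_day
    step = pd.Timedelta(days=1) / params.readings_per_day
    ts = start + step * np.arange(n)
    ts = pd.DatetimeIndex(ts)

    doy = ts.dayofyear.to_numpy() + ts.hour.to_numpy() / 24.0
    annual = params.annual_mean + params.annual_amplitude * np.cos(
        2 * np.pi * (doy - _ANNUAL_PEAK_DOY) / 365.25
    )
    hour = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    diurnal = params.diurnal_amplitude * np.cos(
        2 * np.pi * (hour - _DIURNAL_PEAK_HOUR) / 24.0
    )

    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed))
    phi = params.noise_autocorr
    innov = rng.standard_normal(n) * params.noise_sd * np.sqrt(1.0 - phi**2)
    noise = lfilter([1.0], [1.0, -phi], innov)

    raw = annual + diurnal + noise
    clamp_draw = rng.uniform(params.snow_clamp_low, params.snow_clamp_high, size=n)
    temp = np.where(raw < params.snow_clamp_low, clamp_draw, raw)

    return SoilTempSeries(site=site, timestamps=ts, temperatures=temp)
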