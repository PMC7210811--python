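"""Base-temperature and thermal-time estimation from germination curves.

The thermal-time model for sub-optimal temperatures states that the time
t_g for the g-th percentile of a seed lot to germinate at temperature T
satisfies

    1 / t_g  =  (T - T_b) / theta_g        (T_b < T <= T_o)

so the germination rate 1/t_g is linear in T, vanishing at the base
temperature T_b (common to all percentiles) with slope 1/theta_g, the
reciprocal of the percentile's degree-day requirement (degC d).

The estimation procedure:

1. interpolate percentile times t_g (g = 10..90% in steps of 10) from the
   pooled cumulative germination curve at each incubation temperature;
2. regress 1/t_g on T by OLS within a candidate sub-optimal temperature
   range; choose the range with the smallest pooled residual variance;
3. T_b = mean (+/- sample SD) of the per-percentile x-intercepts whose
   regression slope is significant (two-sided t test, p < alpha);
4. refit each percentile constrained through T_b (least squares through the
   origin on T - T_b); theta_g is the reciprocal slope, theta50 the g = 50
   value.

Conditions where germination is too sparse for any significant fit (too few
attained percentiles) yield no T_b - dormancy was not sufficiently released.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .germination_data import GerminationCurve, GerminationRecord, pool_curve

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES: tuple[int, ...] = tuple(range(10, 100, 10))


class ThermalTimeError(ValueError):
    """Raised when an estimation step has no usable input."""


# ---------------------------------------------------------------------------
# Percentile germination times
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PercentileTimes:
    """Interpolated times (days) to reach each germination percentile.

    ``times[g]`` is None when the condition never attained g% germination.
    """

    site: str
    pretreatment_days: int
    temperature_c: float
    times: Mapping[int, float | None]

    def attained(self) -> list[int]:
        return [g for g, t in self.times.items() if t is not None]


def percentile_times(
    curve: GerminationCurve, percentiles: Sequence[int] = DEFAULT_PERCENTILES
) -> PercentileTimes:
    """Linear interpolation of time vs cumulative percentage.

    The curve is anchored at (day 0, 0%). A percentile exactly equal to an
    observed value gets that observation's day (the earliest, if a plateau
    sits at the value); a percentile above the final percentage is not
    attained.
    """
    days = np.asarray(curve.times, dtype=float)
    pct = np.asarray(curve.cumulative_fraction, dtype=float) * 100.0
    if days.size == 0:
        raise ThermalTimeError("empty curve")
    if days[0] > 0:
        days = np.concatenate([[0.0], days])
        pct = np.concatenate([[0.0], pct])
    out: dict[int, float | None] = {}
    eps = 1e-9
    for g in percentiles:
        if pct[-1] < g - eps:
            out[g] = None
            continue
        exact = np.flatnonzero(np.abs(pct - g) <= eps)
        if exact.size:
            out[g] = float(days[exact[0]])
            continue
        j = int(np.argmax(pct > g))  # first point strictly above g
        i = j - 1
        while pct[i] > g:  # guard: step over any numerically equal plateau
            i -= 1
        t = days[i] + (g - pct[i]) * (days[j] - days[i]) / (pct[j] - pct[i])
        out[g] = float(t)
    return PercentileTimes(curve.site, curve.pretreatment_days, curve.temperature_c, out)


def times_by_temperature(
    records: Sequence[GerminationRecord],
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
    basis: str = "filled",
) -> dict[float, PercentileTimes]:
    """Pool each temperature's dishes and interpolate percentile times."""
    by_temp: dict[float, list[GerminationRecord]] = {}
    for r in records:
        by_temp.setdefault(r.temperature_c, []).append(r)
    return {
        temp: percentile_times(pool_curve(grp, basis=basis), percentiles)
        for temp, grp in sorted(by_temp.items())
    }


# ---------------------------------------------------------------------------
# Rate-temperature regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateRegression:
    """OLS fit of germination rate 1/t_g (day^-1) on temperature (degC)."""

    percentile: int
    temperatures: tuple[float, ...]
    rates: tuple[float, ...]
    slope: float
    intercept: float
    x_intercept: float
    r_squared: float
    p_value: float
    sse: float

    @property
    def n_points(self) -> int:
        return len(self.temperatures)

    @property
    def temperature_range_max(self) -> float:
        return max(self.temperatures)


def rate_points(
    times_by_temp: Mapping[float, PercentileTimes], g: int, max_temp: float = math.inf
) -> list[tuple[float, float]]:
    """(T, 1/t_g) pairs for one percentile; unattained temperatures excluded."""
    pts = []
    for temp, pt in sorted(times_by_temp.items()):
        if temp > max_temp:
            continue
        t_g = pt.times.get(g)
        if t_g is not None and t_g > 0:
            pts.append((temp, 1.0 / t_g))
    return pts


def fit_rate_regression(points: Sequence[tuple[float, float]], g: int) -> RateRegression:
    """Ordinary least squares of rate on temperature (>= 3 points required)."""
    if len(points) < 3:
        raise ThermalTimeError(
            f"percentile {g}: need >= 3 (T, rate) points, got {len(points)}"
        )
    temps = np.array([p[0] for p in points])
    rates = np.array([p[1] for p in points])
    res = stats.linregress(temps, rates)
    fitted = res.intercept + res.slope * temps
    sse = float(np.sum((rates - fitted) ** 2))
    x_int = -res.intercept / res.slope if res.slope > 0 else math.nan
    return RateRegression(
        percentile=g,
        temperatures=tuple(temps),
        rates=tuple(rates),
        slope=float(res.slope),
        intercept=float(res.intercept),
        x_intercept=float(x_int),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        sse=sse,
    )


# ---------------------------------------------------------------------------
# Sub-optimal range selection
# ---------------------------------------------------------------------------

def select_suboptimal_range(
    times_by_temp: Mapping[float, PercentileTimes],
    candidate_max_temps: Sequence[float] | None = None,
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
    per_percentile: bool = False,
) -> tuple[float, dict[int, RateRegression]]:
    """Choose the sub-optimal upper temperature by smallest residual variance.

    For each candidate upper temperature, every percentile with >= 3 points
    at temperatures <= candidate is fitted; the candidate minimising the
    pooled residual variance (sum SSE / sum (n_i - 2), on the rate scale)
    wins, ties going to the wider range. With ``per_percentile=True`` the
    criterion is the mean of per-percentile residual variances instead.
    """
    all_temps = sorted(times_by_temp)
    if candidate_max_temps is None:
        if len(all_temps) < 3:
            raise ThermalTimeError("need >= 3 tested temperatures")
        floor = all_temps[2]  # third-lowest tested temperature
        attainable = [t for t in all_temps if times_by_temp[t].attained()]
        candidate_max_temps = [t for t in attainable if t >= floor]
    if not candidate_max_temps:
        raise ThermalTimeError("no candidate sub-optimal upper temperatures")

    best: tuple[float, dict[int, RateRegression]] | None = None
    best_var = math.inf
    for cand in sorted(candidate_max_temps):
        fits: dict[int, RateRegression] = {}
        sse_sum = 0.0
        df_sum = 0
        for g in percentiles:
            pts = rate_points(times_by_temp, g, max_temp=cand)
            if len(pts) < 3:
                logger.info("candidate %.1f: percentile %d skipped (<3 points)", cand, g)
                continue
            reg = fit_rate_regression(pts, g)
            fits[g] = reg
            sse_sum += reg.sse
            df_sum += reg.n_points - 2
        if not fits or df_sum <= 0:
            continue
        if per_percentile:
            pooled = float(
                np.mean([f.sse / (f.n_points - 2) for f in fits.values() if f.n_points > 2])
            )
        else:
            pooled = sse_sum / df_sum
        # tie broken toward the wider range: ascending scan replaces on equality
        if pooled <= best_var + 1e-12:
            best_var = pooled
            best = (cand, fits)
    if best is None:
        raise ThermalTimeError("no candidate range yields a valid percentile fit")
    logger.info("chosen sub-optimal max %.1f degC (pooled residual var %.3g)", best[0], best_var)
    return best


# ---------------------------------------------------------------------------
# Base temperature and constrained thermal times
# ---------------------------------------------------------------------------

def estimate_Tb(
    regressions: Mapping[int, RateRegression], alpha: float = 0.05
) -> tuple[float, float, tuple[int, ...]] | None:
    """Mean +/- sample SD of x-intercepts over percentiles with p < alpha.

    Returns None when no regression qualifies (dormancy not released enough
    for the rate-temperature relation to emerge).
    """
    xs = []
    used = []
    for g in sorted(regressions):
        reg = regressions[g]
        if reg.p_value < alpha and reg.slope > 0 and math.isfinite(reg.x_intercept):
            xs.append(reg.x_intercept)
            used.append(g)
        else:
            logger.info("percentile %d excluded from T_b (p=%.3g)", g, reg.p_value)
    if not xs:
        return None
    arr = np.asarray(xs)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd, tuple(used)


def origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of a line through the origin: sum(xy)/sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ThermalTimeError("degenerate origin fit: sum(x^2) == 0")
    return float(np.sum(x * y) / sxx)


def constrained_thermal_time(
    times_by_temp: Mapping[float, PercentileTimes],
    T_b: float,
    max_temp: float = math.inf,
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
) -> dict[int, float | None]:
    """Per-percentile theta_g from refits constrained through T_b.

    Each percentile's rates are regressed through the origin on (T - T_b)
    using the sub-optimal points; theta_g = 1/slope (degC d). Percentiles
    with no points, no point above T_b, or a non-positive slope get None.
    """
    out: dict[int, float | None] = {}
    for g in percentiles:
        pts = [(t, r) for t, r in rate_points(times_by_temp, g, max_temp) if t > T_b]
        if not pts:
            out[g] = None
            continue
        x = np.array([t - T_b for t, _ in pts])
        y = np.array([r for _, r in pts])
        b = origin_slope(x, y)
        if b <= 0:
            logger.info("percentile %d: non-positive constrained slope, theta undefined", g)
            out[g] = None
        else:
            out[g] = 1.0 / b
    return out


# ---------------------------------------------------------------------------
# Per-condition orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalParams:
    """Thermal-time parameter estimates for one site x pretreatment."""

    site: str
    pretreatment_days: int
    T_b_mean: float | None
    T_b_sd: float | None
    theta_g: Mapping[int, float | None]
    theta50: float | None
    suboptimal_max: float | None
    percentiles_used: tuple[int, ...]
    regressions: Mapping[int, RateRegression] = field(default_factory=dict)

    @property
    def available(self) -> bool:
        return self.T_b_mean is not None


def estimate_thermal_params(
    records: Sequence[GerminationRecord],
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
    alpha: float = 0.05,
    basis: str = "filled",
    candidate_max_temps: Sequence[float] | None = None,
    per_percentile: bool = False,
) -> ThermalParams:
    """Full estimate for the records of one site x pretreatment."""
    sites = {r.site for r in records}
    pres = {r.pretreatment_days for r in records}
    if len(sites) != 1 or len(pres) != 1:
        raise ThermalTimeError("records must come from a single site x pretreatment")
    site, pre = sites.pop(), pres.pop()
    tbt = times_by_temperature(records, percentiles, basis=basis)
    unavailable = ThermalParams(site, pre, None, None, {}, None, None, ())
    try:
        sub_max, regs = select_suboptimal_range(
            tbt, candidate_max_temps, percentiles, per_percentile
        )
    except ThermalTimeError as exc:
        logger.info("%s/C%d: %s", site, pre, exc)
        return unavailable
    tb = estimate_Tb(regs, alpha=alpha)
    if tb is None:
        logger.info("%s/C%d: no percentile regression with p < %.2f", site, pre, alpha)
        return unavailable
    tb_mean, tb_sd, used = tb
    theta = constrained_thermal_time(tbt, tb_mean, sub_max, percentiles)
    return ThermalParams(
        site=site,
        pretreatment_days=pre,
        T_b_mean=tb_mean,
        T_b_sd=tb_sd,
        theta_g=theta,
        theta50=theta.get(50),
        suboptimal_max=sub_max,
        percentiles_used=used,
        regressions=regs,
    )


def analyze_experiment(
    records: Sequence[GerminationRecord], **kwargs
) -> list[ThermalParams]:
    """Estimate thermal parameters for every site x pretreatment present."""
    groups: dict[tuple[str, int], list[GerminationRecord]] = {}
    for r in records:
        groups.setdefault((r.site, r.pretreatment_days), []).append(r)
    return [estimate_thermal_params(grp, **kwargs) for _, grp in sorted(groups.items())]


def params_table(params: Sequence[ThermalParams]):
    """Report table: one row per condition; theta rounded to integer degC d."""
    import pandas as pd

    rows = []
    for p in params:
        rows.append(
            {
                "site": p.site,
                "pretreatment_days": p.pretreatment_days,
                "T_b_mean": None if p.T_b_mean is None else round(p.T_b_mean, 2),
                "T_b_sd": None if p.T_b_sd is None else round(p.T_b_sd, 2),
                "suboptimal_max": p.suboptimal_max,
                "theta50": None if p.theta50 is None else int(round(p.theta50)),
                "percentiles_used": ";".join(map(str, p.percentiles_used)),
            }
        )
    return pd.DataFrame(rows)
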