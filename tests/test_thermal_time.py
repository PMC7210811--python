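"""Percentile interpolation, rate regressions, T_b and theta estimation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from germtt import (
    GerminationCurve,
    ThermalTimeError,
    analyze_experiment,
    constrained_thermal_time,
    estimate_Tb,
    estimate_thermal_params,
    fit_rate_regression,
    percentile_times,
    select_suboptimal_range,
    times_by_temperature,
)
from germtt.thermal_time import PercentileTimes, origin_slope, rate_points


def curve(times, fractions, temp=15.0):
    return GerminationCurve(
        site="IS", pretreatment_days=60, temperature_c=temp,
        times=tuple(times), cumulative_fraction=tuple(fractions),
        denominator_total=100,
    )


# ---------------------------------------------------------------------------
# Brute-force SSE oracles (independent of the fitting code under test)
# ---------------------------------------------------------------------------

def grid_min_sse_line(x, y, rounds=10, half_width=2.0, n_grid=61):
    """Minimise SSE of y = c + b (x - xbar) over a shrinking 2-D grid.

    Centring x decorrelates the two parameters so the grid refinement cannot
    drift along the intercept-slope valley; the uncentred intercept is
    recovered as a = c - b xbar.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc = x - x.mean()
    b0 = (y[-1] - y[0]) / (x[-1] - x[0])
    c0 = y.mean()
    wc, wb = half_width * (abs(c0) + 1), half_width * (abs(b0) + 1)
    for _ in range(rounds):
        cc = np.linspace(c0 - wc, c0 + wc, n_grid)
        bb = np.linspace(b0 - wb, b0 + wb, n_grid)
        sse = ((y[None, None, :] - cc[:, None, None] - bb[None, :, None] * xc) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        c0, b0 = cc[i], bb[j]
        wc /= 10.0
        wb /= 10.0
    return c0 - b0 * x.mean(), b0


def grid_min_sse_origin(x, y, rounds=6):
    """Minimise SSE of y = b x over a shrinking 1-D grid."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    b0 = y.mean() / x.mean()
    w = 2.0 * (abs(b0) + 1)
    for _ in range(rounds):
        bb = np.linspace(b0 - w, b0 + w, 201)
        sse = ((y[None, :] - bb[:, None] * x) ** 2).sum(-1)
        b0 = bb[int(np.argmin(sse))]
        w /= 20.0
    return b0


# ---------------------------------------------------------------------------
# Percentile times
# ---------------------------------------------------------------------------

def test_midpoint_interpolation():
    pt = percentile_times(curve([5.0, 10.0], [0.40, 0.60]), percentiles=(50,))
    assert pt.times[50] == pytest.approx(7.5)


def test_percentile_above_final_not_attained():
    pt = percentile_times(curve([5.0, 10.0], [0.30, 0.45]), percentiles=(40, 50))
    assert pt.times[50] is None
    assert pt.times[40] is not None


def test_exact_observed_value_takes_earliest_day():
    # 50% is reached exactly at day 6 and stays flat through day 9
    pt = percentile_times(curve([3.0, 6.0, 9.0, 12.0], [0.2, 0.5, 0.5, 0.8]),
                          percentiles=(50,))
    assert pt.times[50] == 6.0


def test_times_increase_with_percentile():
    pt = percentile_times(curve([2.0, 5.0, 9.0, 20.0], [0.1, 0.4, 0.7, 0.9]))
    attained = [pt.times[g] for g in sorted(pt.times) if pt.times[g] is not None]
    assert attained == sorted(attained)


def test_dense_simulated_curve_recovers_closed_form_time(recovery_records):
    """theta50 = 120 degC d at 15 degC above T_b = 0 gives t_50 ~ 8.0 d."""
    recs = [r for r in recovery_records if r.temperature_c == 15.0]
    tbt = times_by_temperature(recs, percentiles=(50,))
    t50 = tbt[15.0].times[50]
    # released fraction ~1 here, so the filled-seed median is theta50's percentile
    assert t50 == pytest.approx(8.0, abs=0.5)


# ---------------------------------------------------------------------------
# Rate regression
# ---------------------------------------------------------------------------

def test_exact_line_regression():
    reg = fit_rate_regression([(5.0, 0.1), (10.0, 0.2), (15.0, 0.3)], g=50)
    assert reg.slope == pytest.approx(0.02)
    assert reg.x_intercept == pytest.approx(0.0, abs=1e-12)
    assert reg.r_squared == pytest.approx(1.0)
    assert reg.temperature_range_max == 15.0


def test_regression_requires_three_points():
    with pytest.raises(ThermalTimeError, match=">= 3"):
        fit_rate_regression([(5.0, 0.1), (10.0, 0.2)], g=50)


def test_ols_matches_brute_force_grid_with_duplicate_temperatures():
    pts = [(5.0, 0.11), (10.0, 0.19), (10.0, 0.23), (15.0, 0.28), (20.0, 0.44)]
    reg = fit_rate_regression(pts, g=50)
    a, b = grid_min_sse_line([p[0] for p in pts], [p[1] for p in pts])
    assert reg.intercept == pytest.approx(a, abs=1e-6)
    assert reg.slope == pytest.approx(b, abs=1e-6)


def test_origin_fit_matches_brute_force_grid():
    x = np.array([4.0, 9.0, 14.0, 19.0])
    y = np.array([0.031, 0.080, 0.113, 0.162])
    assert origin_slope(x, y) == pytest.approx(grid_min_sse_origin(x, y), abs=1e-6)


# ---------------------------------------------------------------------------
# Sub-optimal range selection
# ---------------------------------------------------------------------------

def synthetic_times(rate_fn, temps, percentiles=(30, 50, 70)):
    out = {}
    for T in temps:
        times = {}
        for g in percentiles:
            r = rate_fn(T, g)
            times[g] = (1.0 / r) if r and r > 0 else None
        out[T] = PercentileTimes("IS", 60, T, times)
    return out


def test_rate_collapse_above_20_excludes_25():
    """Rates exactly linear up to 20 degC then collapsing at 25 degC: the
    selection must stop the sub-optimal range at 20."""
    def rate(T, g):
        theta = {30: 100.0, 50: 120.0, 70: 140.0}[g]
        if T <= 20.0:
            return T / theta
        return 5.0 / theta  # collapse: rate falls back to its 5-degC value
    tbt = synthetic_times(rate, [5.0, 10.0, 15.0, 20.0, 25.0])
    chosen, fits = select_suboptimal_range(tbt, candidate_max_temps=[15.0, 20.0, 25.0])
    assert chosen == 20.0
    # including 25 inflates the pooled SSE by orders of magnitude
    _, fits25 = select_suboptimal_range(tbt, candidate_max_temps=[25.0])
    assert sum(f.sse for f in fits25.values()) > 100 * sum(f.sse for f in fits.values())


def test_single_candidate_is_chosen():
    def rate(T, g):
        return T / 120.0
    tbt = synthetic_times(rate, [5.0, 10.0, 15.0])
    chosen, _ = select_suboptimal_range(tbt, candidate_max_temps=[15.0])
    assert chosen == 15.0


def test_tie_broken_toward_wider_range():
    def rate(T, g):  # perfectly linear everywhere: every candidate fits exactly
        return T / 120.0
    tbt = synthetic_times(rate, [5.0, 10.0, 15.0, 20.0])
    chosen, _ = select_suboptimal_range(tbt, candidate_max_temps=[15.0, 20.0])
    assert chosen == 20.0


def test_no_valid_candidate_errors():
    tbt = synthetic_times(lambda T, g: None, [5.0, 10.0, 15.0])
    with pytest.raises(ThermalTimeError):
        select_suboptimal_range(tbt, candidate_max_temps=[15.0])


# ---------------------------------------------------------------------------
# T_b and constrained thermal time
# ---------------------------------------------------------------------------

def test_tb_mean_and_sd_of_x_intercepts():
    regs = {
        30: fit_rate_regression([(5.0, 3.0 / 120), (10.0, 8.0 / 120), (15.0, 13.0 / 120)], 30),
        50: fit_rate_regression([(5.0, 1.0 / 120), (10.0, 6.0 / 120), (15.0, 11.0 / 120)], 50),
    }
    # exact lines with x-intercepts 2.0 and 4.0
    res = estimate_Tb(regs)
    assert res is not None
    tb, sd, used = res
    assert tb == pytest.approx(3.0)
    assert sd == pytest.approx(math.sqrt(2.0), abs=1e-9)
    assert used == (30, 50)


def test_tb_unavailable_when_nothing_significant():
    # 3 points of pure noise around a flat rate: slope not significant
    regs = {50: fit_rate_regression([(5.0, 0.10), (10.0, 0.08), (15.0, 0.11)], 50)}
    assert regs[50].p_value >= 0.05
    assert estimate_Tb(regs) is None


def test_constrained_single_point():
    tbt = {15.0: PercentileTimes("IS", 60, 15.0, {50: 8.0})}
    theta = constrained_thermal_time(tbt, T_b=0.0, percentiles=(50,))
    assert theta[50] == pytest.approx(120.0)


def test_constrained_two_point_hand_arithmetic():
    """(10 degC, 1/12 d^-1), (15 degC, 1/8 d^-1) through T_b = 0:
    b = (10/12 + 15/8)/325 = 1/120 exactly, so theta50 = 120 degC d."""
    tbt = {10.0: PercentileTimes("IS", 60, 10.0, {50: 12.0}),
           15.0: PercentileTimes("IS", 60, 15.0, {50: 8.0})}
    theta = constrained_thermal_time(tbt, T_b=0.0, percentiles=(50,))
    assert theta[50] == pytest.approx(120.0, abs=1e-9)
    x = np.array([10.0, 15.0])
    y = np.array([1 / 12, 1 / 8])
    assert 1.0 / grid_min_sse_origin(x, y) == pytest.approx(120.0, abs=1e-4)


def test_consistency_exact_linear_rates_reproduce_times():
    """When input rates are exactly (T - T_b)/theta, the fitted parameters
    reproduce every input t_g exactly."""
    T_b_true, theta_true = 2.0, 110.0
    temps = [5.0, 10.0, 15.0, 20.0]
    tbt = {
        T: PercentileTimes("IS", 60, T, {50: theta_true / (T - T_b_true)})
        for T in temps
    }
    reg = fit_rate_regression(rate_points(tbt, 50), 50)
    assert reg.x_intercept == pytest.approx(T_b_true, abs=1e-9)
    theta = constrained_thermal_time(tbt, reg.x_intercept, percentiles=(50,))[50]
    for T in temps:
        assert theta / (T - reg.x_intercept) == pytest.approx(
            tbt[T].times[50], rel=1e-9
        )


# ---------------------------------------------------------------------------
# End-to-end on simulated experiments
# ---------------------------------------------------------------------------

def test_parameter_recovery(recovery_records):
    """10,000 seeds per temperature, sub-optimal range only: the pipeline
    recovers T_b within 0.5 degC and theta50 within 10%."""
    params = estimate_thermal_params(recovery_records)
    assert params.available
    assert abs(params.T_b_mean - 0.0) <= 0.5
    assert abs(params.theta50 - 120.0) / 120.0 <= 0.10


def test_sparse_conditions_yield_no_tb(paper_records):
    """Unstratified and lightly stratified lots (C0/C15) germinate too little
    for any percentile regression, so T_b is unavailable there."""
    all_params = {(p.site, p.pretreatment_days): p for p in analyze_experiment(paper_records)}
    for site in ("IS", "TM"):
        assert not all_params[(site, 0)].available
        assert not all_params[(site, 15)].available
        assert all_params[(site, 90)].available


def test_qualifying_percentiles_never_increase_with_less_stratification(paper_records):
    all_params = {(p.site, p.pretreatment_days): p for p in analyze_experiment(paper_records)}
    for site in ("IS", "TM"):
        counts = [len(all_params[(site, s)].percentiles_used) for s in (0, 15, 30, 60, 90)]
        assert counts == sorted(counts)
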