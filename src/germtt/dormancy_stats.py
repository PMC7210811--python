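"""Inferential statistics for the factorial germination experiment.

Final germination proportions (per dish, with filled seeds as binomial
denominators) are analysed with a quasi-binomial GLM (logit link): the
dispersion is estimated from the Pearson chi-square, and terms are tested
with sequential (type-I) F tests on the analysis-of-deviance table, the
appropriate procedure when the scale parameter is empirical. Post-hoc
pairwise contrasts use t tests with the SD pooled across all factor levels
and Bonferroni-adjusted p values. Base-temperature estimates (per-percentile
x-intercepts) are compared across conditions with a quasi-Poisson GLM
(log link); because x-intercepts can be negative, values are shifted
positive first and the shift is reported.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


class StatsError(ValueError):
    """Raised for degenerate or non-converging model fits."""


@dataclass(frozen=True)
class DevianceTable:
    """Sequential analysis of deviance with empirical-dispersion F tests."""

    table: pd.DataFrame  # rows: NULL then one per term
    dispersion: float
    family: str
    shift: float = 0.0  # applied to the response before a log link, if any

    @property
    def null_deviance(self) -> float:
        return float(self.table.iloc[0]["resid_deviance"])

    @property
    def residual_deviance(self) -> float:
        return float(self.table.iloc[-1]["resid_deviance"])

    def p_value(self, term: str) -> float:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in deviance table")
        return float(row["p_value"].iloc[0])


def _fit_glm(formula: str, data: pd.DataFrame, family, var_weights=None,
             check_separation: bool = False):
    model = smf.glm(formula, data=data, family=family, var_weights=var_weights)
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise StatsError(
            f"GLM {formula!r} failed to converge in 100 iterations "
            f"(deviance trace tail: {res.fit_history['deviance'][-3:]})"
        )
    if check_separation and np.any(np.abs(res.params) > 15):
        warnings.warn(
            f"GLM {formula!r}: extreme coefficients suggest (quasi-)separation",
            stacklevel=2,
        )
    return res


def _sequential_anova(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    family,
    var_weights=None,
) -> tuple[pd.DataFrame, float]:
    """Type-I deviance decomposition by nested refits, F tests vs dispersion."""
    rhs = "1"
    fits = [_fit_glm(f"{response} ~ {rhs}", data, family, var_weights)]
    for i, term in enumerate(terms):
        rhs = f"{rhs} + {term}"
        fits.append(
            _fit_glm(f"{response} ~ {rhs}", data, family, var_weights,
                     check_separation=(i == len(terms) - 1))
        )
    full = fits[-1]
    dispersion = float(full.pearson_chi2 / full.df_resid)
    rows = [
        {
            "term": "NULL",
            "df": np.nan,
            "deviance": np.nan,
            "resid_df": int(fits[0].df_resid),
            "resid_deviance": float(fits[0].deviance),
            "F": np.nan,
            "p_value": np.nan,
        }
    ]
    for term, prev, cur in zip(terms, fits, fits[1:]):
        ddf = int(prev.df_resid - cur.df_resid)
        ddev = max(float(prev.deviance - cur.deviance), 0.0)  # clip FP round-off
        if ddf <= 0:
            f_stat, p = np.nan, np.nan
        elif dispersion > 1e-12:
            f_stat = (ddev / ddf) / dispersion
            p = float(stats.f.sf(f_stat, ddf, full.df_resid))
        else:
            # saturated fit: no residual variation to test against
            f_stat, p = (0.0, 1.0) if ddev < 1e-12 else (np.inf, 0.0)
        rows.append(
            {
                "term": term,
                "df": ddf,
                "deviance": ddev,
                "resid_df": int(cur.df_resid),
                "resid_deviance": float(cur.deviance),
                "F": f_stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows), dispersion


# ---------------------------------------------------------------------------
# Quasi-binomial GLM on germination proportions
# ---------------------------------------------------------------------------

def dish_table(records, basis: str = "filled") -> pd.DataFrame:
    """Per-dish analysis frame: factors, proportion germinated, denominator."""
    rows = []
    for r in records:
        denom = r.denominator(basis)
        if denom <= 0:
            continue
        rows.append(
            {
                "site": r.site,
                "pretreatment_days": r.pretreatment_days,
                "temperature_c": r.temperature_c,
                "dish": r.dish,
                "proportion": r.final_germinated / denom,
                "denominator": denom,
            }
        )
    if not rows:
        raise StatsError("no dishes with a positive denominator")
    return pd.DataFrame(rows)


DEFAULT_TERMS: tuple[str, ...] = (
    "C(pretreatment_days)",
    "C(temperature_c)",
    "C(site)",
    "C(pretreatment_days):C(temperature_c)",
    "C(pretreatment_days):C(site)",
    "C(site):C(temperature_c)",
    "C(pretreatment_days):C(site):C(temperature_c)",
)


def fit_proportion_glm(
    data: pd.DataFrame, terms: Sequence[str] = DEFAULT_TERMS
) -> DevianceTable:
    """Quasi-binomial (logit) sequential analysis of deviance.

    ``data`` is a :func:`dish_table` frame: the response is the per-dish
    germinated proportion weighted by its filled-seed denominator, so the
    deviance matches a binomial GLM on (germinated, not germinated) counts.
    F = (delta deviance / delta df) / dispersion with dispersion = Pearson
    chi-square / residual df of the full model.
    """
    for col in ("proportion", "denominator"):
        if col not in data.columns:
            raise StatsError(f"missing column {col!r}; build input with dish_table()")
    table, dispersion = _sequential_anova(
        data,
        "proportion",
        list(terms),
        sm.families.Binomial(),
        var_weights=np.asarray(data["denominator"], dtype=float),
    )
    return DevianceTable(table=table, dispersion=dispersion, family="quasi-binomial")


# ---------------------------------------------------------------------------
# Pairwise t tests with pooled SD and Bonferroni adjustment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseMatrix:
    """Symmetric matrix of Bonferroni-adjusted p values between factor levels."""

    levels: tuple
    p_values: pd.DataFrame
    method: str = "bonferroni"

    def p(self, a, b) -> float:
        return float(self.p_values.loc[a, b])


def pairwise_bonferroni(values: Sequence[float], groups: Sequence) -> PairwiseMatrix:
    """Two-sample t tests with the residual SD pooled across *all* levels.

    Mirrors the classical pooled-SD pairwise procedure: t = (m_i - m_j) /
    (s_pool * sqrt(1/n_i + 1/n_j)) with df = N - k, raw p multiplied by the
    number of comparisons and capped at 1. Levels with fewer than two
    observations are excluded with a warning.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    sizes = df.groupby("group").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding levels with < 2 observations: {small}", stacklevel=2)
        df = df[~df["group"].isin(small)]
    levels = sorted(df["group"].unique().tolist())
    if len(levels) < 2:
        raise StatsError("need >= 2 levels with >= 2 observations each")
    n_tot = len(df)
    k = len(levels)
    means = df.groupby("group")["value"].mean()
    ss_within = float(
        df.groupby("group")["value"].apply(lambda v: ((v - v.mean()) ** 2).sum()).sum()
    )
    dof = n_tot - k
    s_pool = np.sqrt(ss_within / dof) if dof > 0 else np.nan
    pairs = list(itertools.combinations(levels, 2))
    mat = pd.DataFrame(np.nan, index=levels, columns=levels)
    for a, b in pairs:
        na, nb = sizes[a], sizes[b]
        if s_pool == 0:
            p_raw = 1.0 if means[a] == means[b] else 0.0
        else:
            t = (means[a] - means[b]) / (s_pool * np.sqrt(1 / na + 1 / nb))
            p_raw = 2 * stats.t.sf(abs(t), dof)
        p_adj = min(1.0, p_raw * len(pairs))
        mat.loc[a, b] = p_adj
        mat.loc[b, a] = p_adj
    return PairwiseMatrix(levels=tuple(levels), p_values=mat)


# ---------------------------------------------------------------------------
# Base-temperature comparison (quasi-Poisson, log link)
# ---------------------------------------------------------------------------

def compare_Tb(tb_values: pd.DataFrame, terms: Sequence[str] | None = None) -> DevianceTable:
    """Quasi-Poisson GLM on per-percentile x-intercepts across conditions.

    ``tb_values`` needs columns ``x_intercept``, ``pretreatment_days`` and
    ``site`` (one row per qualifying percentile per condition). A log link
    cannot take non-positive values, so when any x-intercept is <= 0 the
    response is shifted by ``1 + |min|`` first; the shift is recorded on the
    result and flagged with a warning.
    """
    required = {"x_intercept", "pretreatment_days", "site"}
    if not required <= set(tb_values.columns):
        raise StatsError(f"tb_values needs columns {sorted(required)}")
    if tb_values["pretreatment_days"].nunique() < 2 and tb_values["site"].nunique() < 2:
        raise StatsError("need x-intercepts from >= 2 conditions")
    if float(tb_values["x_intercept"].std(ddof=0)) == 0.0:
        raise StatsError("all x-intercepts identical: comparison is degenerate")
    data = tb_values.copy()
    shift = 0.0
    mn = float(data["x_intercept"].min())
    if mn <= 0:
        shift = 1.0 + abs(mn)
        warnings.warn(
            f"x-intercepts span non-positive values; shifting by +{shift:.3f} "
            "before the log link",
            stacklevel=2,
        )
    data["shifted_tb"] = data["x_intercept"] + shift
    if terms is None:
        terms = ["C(pretreatment_days)", "C(site)"]
    table, dispersion = _sequential_anova(
        data, "shifted_tb", list(terms), sm.families.Poisson()
    )
    return DevianceTable(
        table=table, dispersion=dispersion, family="quasi-poisson", shift=shift
    )


def tb_frame(params_list) -> pd.DataFrame:
    """Collect per-percentile x-intercepts from ThermalParams estimates."""
    rows = []
    for p in params_list:
        for g in p.percentiles_used:
            rows.append(
                {
                    "site": p.site,
                    "pretreatment_days": p.pretreatment_days,
                    "percentile": g,
                    "x_intercept": p.regressions[g].x_intercept,
                }
            )
    return pd.DataFrame(rows)
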