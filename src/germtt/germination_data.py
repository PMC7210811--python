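"""Germination scoring records and cumulative germination curves.

A germination trial scores a Petri dish of seeds repeatedly (cumulative
germinated count per observation day) and ends with a cut test that splits
the non-germinated seeds into empty and viable-but-ungerminated. Final
germination percentages are computed on the *filled* seeds (sown minus
empty), the convention used throughout this package; a viable-seed basis
(germinated + viable ungerminated as denominator) is available via the
``basis`` switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns of the germination CSV dialect, one row per dish x observation.
CSV_COLUMNS = [
    "site",
    "pretreatment_days",
    "temperature_c",
    "dish",
    "day",
    "cum_germinated",
    "sown",
    "empty",
    "viable_ungerminated",
]


class GerminationDataError(ValueError):
    """Raised when a record violates the seed-accounting invariants."""


@dataclass(frozen=True)
class GerminationRecord:
    """One dish's germination time-course plus end-of-test cut-test counts.

    Invariants (checked by :meth:`validate`): observation days strictly
    increasing, cumulative counts non-decreasing, all counts >= 0, and the
    accounting identity ``final cumulative + empty + viable_ungerminated ==
    sown``.
    """

    site: str
    pretreatment_days: int
    temperature_c: float
    dish: str
    observations: tuple[tuple[float, int], ...]
    sown: int
    empty: int
    viable_ungerminated: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "observations", tuple((float(d), int(c)) for d, c in self.observations)
        )
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def days(self) -> np.ndarray:
        return np.array([d for d, _ in self.observations], dtype=float)

    @property
    def cumulative(self) -> np.ndarray:
        return np.array([c for _, c in self.observations], dtype=int)

    @property
    def final_germinated(self) -> int:
        return int(self.observations[-1][1]) if self.observations else 0

    @property
    def filled(self) -> int:
        """Seeds with embryo tissue: sown minus cut-test empties."""
        return self.sown - self.empty

    def denominator(self, basis: str = "filled") -> int:
        if basis == "filled":
            return self.filled
        if basis == "viable":
            return self.final_germinated + self.viable_ungerminated
        raise ValueError(f"unknown basis {basis!r}; expected 'filled' or 'viable'")

    def condition(self) -> tuple[str, int, float]:
        return (self.site, self.pretreatment_days, self.temperature_c)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        label = f"dish {self.site}/{self.pretreatment_days}d/{self.temperature_c}C/{self.dish}"
        if not self.observations:
            raise GerminationDataError(f"{label}: no observations")
        days = self.days
        if np.any(days < 0):
            raise GerminationDataError(f"{label}: negative observation day")
        if np.any(np.diff(days) <= 0):
            raise GerminationDataError(f"{label}: observation days not strictly increasing")
        cum = self.cumulative
        if np.any(cum < 0):
            raise GerminationDataError(f"{label}: negative cumulative count")
        if np.any(np.diff(cum) < 0):
            raise GerminationDataError(f"{label}: cumulative counts decrease")
        for name, v in (
            ("sown", self.sown),
            ("empty", self.empty),
            ("viable_ungerminated", self.viable_ungerminated),
        ):
            if v < 0:
                raise GerminationDataError(f"{label}: {name} < 0")
        if self.final_germinated + self.empty + self.viable_ungerminated != self.sown:
            raise GerminationDataError(
                f"{label}: accounting identity violated: final germinated "
                f"{self.final_germinated} + empty {self.empty} + viable ungerminated "
                f"{self.viable_ungerminated} != sown {self.sown}"
            )


@dataclass(frozen=True)
class GerminationCurve:
    """Pooled cumulative germination for one site x pretreatment x temperature.

    ``cumulative_fraction`` is the fraction of the pooled denominator (filled
    seeds by default) germinated by each time; it is non-decreasing and
    bounded by 1.
    """

    site: str
    pretreatment_days: int
    temperature_c: float
    times: tuple[float, ...]
    cumulative_fraction: tuple[float, ...]
    denominator_total: int
    basis: str = "filled"

    def __post_init__(self) -> None:
        frac = np.asarray(self.cumulative_fraction, dtype=float)
        if frac.size == 0:
            raise GerminationDataError("empty germination curve")
        if np.any(np.diff(frac) < -1e-12) or frac[-1] > 1 + 1e-12:
            raise GerminationDataError("curve fractions must be non-decreasing and <= 1")

    @property
    def final_fraction(self) -> float:
        return float(self.cumulative_fraction[-1])


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_records(path: str | Path) -> list[GerminationRecord]:
    """Read germination records from the long-format CSV dialect.

    One row per dish x observation; cut-test counts are repeated on each row
    of a dish (a companion wide summary is also accepted as long as the
    columns are present). Validation errors name the offending dish.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise GerminationDataError(f"{path}: missing columns {missing}")
    records: list[GerminationRecord] = []
    keys = ["site", "pretreatment_days", "temperature_c", "dish"]
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("day")
        for col in ("sown", "empty", "viable_ungerminated"):
            if grp[col].nunique() != 1:
                raise GerminationDataError(
                    f"dish {key}: column {col!r} not constant across rows"
                )
        records.append(
            GerminationRecord(
                site=str(key[0]),
                pretreatment_days=int(key[1]),
                temperature_c=float(key[2]),
                dish=str(key[3]),
                observations=tuple(zip(grp["day"], grp["cum_germinated"])),
                sown=int(grp["sown"].iloc[0]),
                empty=int(grp["empty"].iloc[0]),
                viable_ungerminated=int(grp["viable_ungerminated"].iloc[0]),
            )
        )
    return records


def write_records(records: Iterable[GerminationRecord], path: str | Path) -> None:
    """Write records in the long CSV dialect (inverse of :func:`read_records`)."""
    rows = []
    for r in records:
        for day, cum in r.observations:
            rows.append(
                {
                    "site": r.site,
                    "pretreatment_days": r.pretreatment_days,
                    "temperature_c": r.temperature_c,
                    "dish": r.dish,
                    "day": day,
                    "cum_germinated": cum,
                    "sown": r.sown,
                    "empty": r.empty,
                    "viable_ungerminated": r.viable_ungerminated,
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Final germination percentage
# ---------------------------------------------------------------------------

def final_germination(
    records: Sequence[GerminationRecord], basis: str = "filled"
) -> tuple[float, float]:
    """Mean +/- sample SD (n-1) of per-dish final germination percentages.

    Per-dish percentage = 100 * final cumulative / denominator, where the
    denominator excludes empty seeds (``basis='filled'``). Dishes whose
    denominator is zero are excluded and logged. SD is nan for a single dish.
    """
    if not records:
        raise GerminationDataError("no records supplied")
    pcts = []
    for r in records:
        denom = r.denominator(basis)
        if denom <= 0:
            logger.warning("excluding dish %s: zero %s seeds", r.dish, basis)
            continue
        pcts.append(100.0 * r.final_germinated / denom)
    if not pcts:
        raise GerminationDataError("all dishes have a zero denominator")
    arr = np.asarray(pcts)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return float(np.mean(arr)), sd


# ---------------------------------------------------------------------------
# Pooled curves
# ---------------------------------------------------------------------------

def pool_curve(
    records: Sequence[GerminationRecord], basis: str = "filled"
) -> GerminationCurve:
    """Pool dishes of one condition into a single cumulative-fraction curve.

    The time axis is the union of all observation days; each dish's count is
    carried forward onto days it was not scored (its schedule is a step
    function). Pooled fraction(t) = sum of dish counts at t / sum of dish
    denominators.
    """
    if not records:
        raise GerminationDataError("no records supplied")
    conds = {r.condition() for r in records}
    if len(conds) > 1:
        raise GerminationDataError(f"records span multiple conditions: {sorted(conds)}")
    denom = sum(r.denominator(basis) for r in records)
    if denom <= 0:
        raise GerminationDataError("pooled denominator is zero")
    times = np.unique(np.concatenate([r.days for r in records]))
    total = np.zeros_like(times)
    for r in records:
        # last observation carried forward; 0 before the first observation
        idx = np.searchsorted(r.days, times, side="right") - 1
        cum = r.cumulative
        total += np.where(idx >= 0, cum[np.clip(idx, 0, None)], 0)
    site, pre, temp = records[0].condition()
    return GerminationCurve(
        site=site,
        pretreatment_days=pre,
        temperature_c=temp,
        times=tuple(times),
        cumulative_fraction=tuple(total / denom),
        denominator_total=denom,
        basis=basis,
    )


# ---------------------------------------------------------------------------
# Condition-level summary (printed-table shape)
# ---------------------------------------------------------------------------

def summary_table(records: Sequence[GerminationRecord], basis: str = "filled") -> pd.DataFrame:
    """Per-condition mean +/- SD final germination, one row per condition.

    Columns: site, pretreatment_days, temperature_c, mean_pct, sd_pct,
    n_dishes. Percentages rounded to 2 decimals in the returned table.
    """
    rows = []
    by_cond: dict[tuple, list[GerminationRecord]] = {}
    for r in records:
        by_cond.setdefault(r.condition(), []).append(r)
    for (site, pre, temp), grp in sorted(by_cond.items()):
        mean, sd = final_germination(grp, basis=basis)
        rows.append(
            {
                "site": site,
                "pretreatment_days": pre,
                "temperature_c": temp,
                "mean_pct": round(mean, 2),
                "sd_pct": round(sd, 2) if np.isfinite(sd) else sd,
                "n_dishes": len(grp),
            }
        )
    return pd.DataFrame(rows)


def min_stratification_for_target(summary: pd.DataFrame, target_pct: float = 50.0) -> int | None:
    """Shortest pretreatment whose best temperature exceeds ``target_pct``.

    Operates on a :func:`summary_table`-shaped frame (any site pooled by max).
    Returns None when no pretreatment reaches the target.
    """
    best = summary.groupby("pretreatment_days")["mean_pct"].max()
    ok = best[best > target_pct]
    return int(ok.index.min()) if not ok.empty else None
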