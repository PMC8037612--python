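"""Lifetime new-cell production from instantaneous S-phase counts.

A single pulse of EdU labels the cohort of cells in S phase at injection
time. Under the assumption that S phase lasts 12 h in all proliferating
cells, a detected count N corresponds to a production rate of 2N new cells
per day (the S-phase pool turns over twice daily). Assuming the count
changes linearly between two sampled ages with counts A and B over C days,
the produced cells integrate to::

    S = ∫ 2·N(t) dt = 2 · (A + B)/2 · C = (A + B) × C

which is the trapezoid rule applied to the daily rate. Months are converted
to days with a fixed convention (default 30 days/month; the printed
reference totals cannot be matched to the last digit under any single
convention, so reproduction is tolerance-based at the 1–2% level). No
extrapolation is made before the first or after the last sampled age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class AgeSchedule:
    """Sampling ages and the time conventions behind the estimate."""

    ages_months: tuple[float, ...] = (2, 4, 8, 12, 30)
    month_days: float = 30.0  # 30.44 for calendar-average months
    s_phase_hours: float = 12.0
    #: EdU circulates for ~1 h before euthanasia; recorded for documentation,
    #: it does not enter the production formula.
    label_window_hours: float = 1.0

    def __post_init__(self) -> None:
        ages = tuple(float(a) for a in self.ages_months)
        if len(ages) < 2 or any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing, with at least two")
        if self.s_phase_hours <= 0 or self.month_days <= 0:
            raise ValueError("s_phase_hours and month_days must be positive")
        self.ages_months = ages

    @property
    def rate_factor(self) -> float:
        """Daily turnovers of the S-phase pool divided by 2 (1 at 12 h)."""
        return 12.0 / self.s_phase_hours


@dataclass
class ProductionTable:
    """Lifetime totals and per-interval production, per mouse series."""

    totals: pd.DataFrame     # index: series + average/stdev; columns: compartments
    intervals: pd.DataFrame  # index: (series, interval); columns: compartments
    schedule: AgeSchedule = field(default_factory=AgeSchedule)


def interval_production(a: float, b: float, days: float) -> float:
    """New cells over one interval: (A + B) × C under a 12-h S phase."""
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if days <= 0:
        raise ValueError("interval length must be positive")
    return (a + b) * days


def daily_production(n: float, s_phase_hours: float = 12.0) -> float:
    """Cells produced per day by a pool of ``n`` S-phase cells."""
    if n < 0:
        raise ValueError("count must be non-negative")
    if s_phase_hours <= 0:
        raise ValueError("s_phase_hours must be positive")
    return n * 24.0 / s_phase_hours


def lifetime_production(
    counts: pd.DataFrame,
    schedule: AgeSchedule | None = None,
) -> ProductionTable:
    """Accumulate interval production over a count table's age series.

    ``counts`` is shaped like the packaged table: a ``mouse`` column of ids
    ``<age>-<series>`` (e.g. ``2M-A``), an ``age_months`` column, and one
    ``<compartment>_npc`` column per compartment. Each series (mouse lineage
    followed across ages) must have a row at every schedule age. Output rows
    are the per-series lifetime totals plus their cross-series average and
    n−1 standard deviation; hierarchy additivity of the inputs carries over
    to every production entry by linearity.
    """
    schedule = schedule or AgeSchedule()
    comps = [c[:-4] for c in counts.columns if c.endswith("_npc")]
    if not comps:
        raise ValueError("counts table has no *_npc columns")
    series_of = counts["mouse"].astype(str).str.rsplit("-", n=1).str[-1]
    factor = schedule.rate_factor

    totals = {}
    intervals: dict[tuple[str, str], dict[str, float]] = {}
    for series in sorted(series_of.unique()):
        rows = counts[series_of == series].set_index("age_months")
        for age in schedule.ages_months:
            if age not in rows.index:
                raise ValueError(f"series {series!r} has no counts at age {age} months")
        tot = {c: 0.0 for c in comps}
        for a0, a1 in zip(schedule.ages_months, schedule.ages_months[1:]):
            days = (a1 - a0) * schedule.month_days
            rec = {}
            for c in comps:
                s = interval_production(float(rows.loc[a0, f"{c}_npc"]),
                                        float(rows.loc[a1, f"{c}_npc"]), days) * factor
                rec[c] = s
                tot[c] += s
            intervals[(series, f"{a0:g}-{a1:g}")] = rec
        totals[series] = tot

    tdf = pd.DataFrame(totals).T[comps]
    tdf.loc["average"] = tdf.mean()
    tdf.loc["stdev"] = tdf.drop(index=["average"]).std(ddof=1)
    idf = pd.DataFrame(intervals).T[comps]
    idf.index.names = ["series", "interval"]
    return ProductionTable(tdf, idf, schedule)


def replacement_summary(
    target_pool: float,
    production: float | None = None,
    daily_rate: float | None = None,
) -> dict[str, float]:
    """Fold coverage of a neuron pool and the days to one full replacement.

    ``fold`` = production / pool (how many times the produced precursors
    could replace the pool); ``days_to_replacement`` = pool / daily rate.
    A zero rate leaves the replacement time undefined (NaN, logged).
    """
    if target_pool <= 0:
        raise ValueError("target_pool must be positive")
    out: dict[str, float] = {}
    if production is not None:
        out["fold"] = production / target_pool
    if daily_rate is not None:
        if daily_rate > 0:
            out["days_to_replacement"] = target_pool / daily_rate
        else:
            logger.warning("zero daily rate: replacement time undefined")
            out["days_to_replacement"] = float("nan")
    return out
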