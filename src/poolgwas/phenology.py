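"""Thermal-time phenology: degree-day flowering traits and plot aggregation.

Flowering phenology is expressed in accumulated thermal time (degree-days,
base 1 degree C): FL_Begin and FL_Full are the thermal time accumulated from
the day of first emergence until, respectively, beginning of flowering and
full flowering. VEG is the vegetative period in calendar days (emergence to
beginning of flowering). Sex determination is a plot score: 1 = dioecious,
2 = mixed, 3 = monoecious; accession values are plot means in [1, 3].

Daily increments use the daily mean temperature clamped at the base
temperature; an optional ceiling cap is available but off by default.
Intervals are half-open in days, [from_date, to_date): the start day
contributes, the event day does not. This makes thermal time exactly
additive over adjacent intervals.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import TRAITS

logger = logging.getLogger(__name__)

BASE_TEMP_C = 1.0


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()


@dataclass
class TemperatureSeries:
    """Daily mean air temperatures (degree C) on strictly consecutive dates."""

    location_id: str
    dates: list[dt.date]
    tmean: np.ndarray

    def __post_init__(self) -> None:
        self.dates = [_as_date(d) for d in self.dates]
        self.tmean = np.asarray(self.tmean, dtype=float)
        if len(self.dates) != len(self.tmean):
            raise ValueError("dates and tmean must have equal length")
        if len(self.dates) < 1:
            raise ValueError("temperature series must cover at least one day")
        for a, b in zip(self.dates, self.dates[1:]):
            if (b - a).days != 1:
                raise ValueError(f"dates not consecutive at {a} -> {b}")
        if not np.all(np.isfinite(self.tmean)):
            raise ValueError("temperatures must be finite")

    @property
    def start(self) -> dt.date:
        return self.dates[0]

    @property
    def end(self) -> dt.date:
        return self.dates[-1]

    def index_of(self, d) -> int:
        d = _as_date(d)
        i = (d - self.start).days
        if i < 0 or i >= len(self.dates):
            raise ValueError(
                f"date {d} outside temperature series for {self.location_id} "
                f"({self.start}..{self.end})"
            )
        return i


def accumulate_thermal_time(
    series: TemperatureSeries,
    from_date,
    to_date,
    base_temp: float = BASE_TEMP_C,
    ceiling: Optional[float] = None,
) -> float:
    """Sum of max(0, tmean - base_temp) over days in [from_date, to_date).

    Returns 0 for an empty interval. With ``ceiling`` set, daily means are
    capped at the ceiling before subtracting the base.
    """
    from_date, to_date = _as_date(from_date), _as_date(to_date)
    if from_date > to_date:
        raise ValueError(f"from_date {from_date} is after to_date {to_date}")
    if from_date == to_date:
        # allow the degenerate interval even at the series edge
        series.index_of(from_date)
        return 0.0
    i = series.index_of(from_date)
    j = series.index_of(to_date - dt.timedelta(days=1)) + 1
    t = series.tmean[i:j]
    if ceiling is not None:
        t = np.minimum(t, ceiling)
    return float(np.maximum(t - base_temp, 0.0).sum())


@dataclass
class PlotPhenologyRecord:
    """One field plot: sowing/emergence/flowering dates and the sex score."""

    location_id: str
    accession_id: str
    plot_id: str
    sowing_date: dt.date
    emergence_date: dt.date
    begin_flowering_date: Optional[dt.date] = None
    full_flowering_date: Optional[dt.date] = None
    sex_score: int = 2

    def __post_init__(self) -> None:
        self.sowing_date = _as_date(self.sowing_date)
        self.emergence_date = _as_date(self.emergence_date)
        if self.begin_flowering_date is not None:
            self.begin_flowering_date = _as_date(self.begin_flowering_date)
        if self.full_flowering_date is not None:
            self.full_flowering_date = _as_date(self.full_flowering_date)
        if self.sowing_date > self.emergence_date:
            raise ValueError("sowing date after emergence date")
        if (
            self.begin_flowering_date is not None
            and self.emergence_date > self.begin_flowering_date
        ):
            raise ValueError("emergence date after begin-flowering date")
        if (
            self.begin_flowering_date is not None
            and self.full_flowering_date is not None
            and self.begin_flowering_date > self.full_flowering_date
        ):
            raise ValueError("begin-flowering date after full-flowering date")
        if self.sex_score not in (1, 2, 3):
            raise ValueError(f"sex_score must be in {{1,2,3}}, got {self.sex_score}")


def compute_flowering_traits(
    record: PlotPhenologyRecord,
    series: TemperatureSeries,
    base_temp: float = BASE_TEMP_C,
    ceiling: Optional[float] = None,
) -> tuple[float, float, float]:
    """(FL_Begin degree-days, FL_Full degree-days, VEG days) for one plot.

    Missing flowering dates (plots that stayed vegetative) propagate as NaN.
    """
    flb = flf = veg = float("nan")
    if record.begin_flowering_date is not None:
        flb = accumulate_thermal_time(
            series, record.emergence_date, record.begin_flowering_date,
            base_temp=base_temp, ceiling=ceiling,
        )
        veg = float((record.begin_flowering_date - record.emergence_date).days)
    if record.full_flowering_date is not None:
        flf = accumulate_thermal_time(
            series, record.emergence_date, record.full_flowering_date,
            base_temp=base_temp, ceiling=ceiling,
        )
    return flb, flf, veg


def aggregate_plots(
    records: Iterable[PlotPhenologyRecord],
    series_by_location: Mapping[str, TemperatureSeries],
    base_temp: float = BASE_TEMP_C,
    ceiling: Optional[float] = None,
) -> pd.DataFrame:
    """Accession x location trait means (the y of the association model).

    Returns a DataFrame indexed by (accession_id, location_id) with columns
    FL_Begin, FL_Full, VEG, Sex_det. Each cell is the arithmetic mean over
    plots with a non-missing value; cells where every plot is missing stay
    NaN and are logged.
    """
    rows = []
    for rec in records:
        series = series_by_location[rec.location_id]
        flb, flf, veg = compute_flowering_traits(
            rec, series, base_temp=base_temp, ceiling=ceiling
        )
        rows.append(
            {
                "accession_id": rec.accession_id,
                "location_id": rec.location_id,
                "FL_Begin": flb,
                "FL_Full": flf,
                "VEG": veg,
                "Sex_det": float(rec.sex_score),
            }
        )
    if not rows:
        raise ValueError("no phenology records to aggregate")
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["accession_id", "location_id"], sort=True)[list(TRAITS)]
        .mean()  # pandas mean skips NaN per cell
    )
    n_missing = int(table.isna().sum().sum())
    if n_missing:
        logger.info("aggregate_plots: %d accession x location cells missing", n_missing)
    return table
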