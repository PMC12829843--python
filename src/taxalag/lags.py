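"""Lag periods, field-trip segmentation and seasonality summaries.

The description timeline of a species is split into three periods, all in
years (day spans divided by 365.25):

* overall  — first type-specimen collection to publication,
* collection — first to last type-specimen collection,
* description (sensu stricto) — last collection to publication,

so overall = collection + description by construction.  Collection events
on the same calendar day count once; events separated by more than
``gap_days`` (default 30) belong to different field trips.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import TypeSeriesRecord

DAYS_PER_YEAR = 365.25
DEFAULT_GAP_DAYS = 30


@dataclass(frozen=True)
class LagDecomposition:
    species: str
    region: str
    genus: str
    overall_y: float
    collection_y: float
    description_y: float
    n_unique_dates: int
    n_trips: int

    def __post_init__(self):
        if self.description_y <= 0:
            raise ValueError(
                f"{self.species}: non-positive description lag "
                f"(should have been excluded upstream)")
        if self.collection_y < 0:
            raise ValueError(f"{self.species}: negative collection span")
        if self.n_trips > self.n_unique_dates:
            raise ValueError("n_trips cannot exceed n_unique_dates")


def unique_sorted_dates(record: TypeSeriesRecord) -> list[dt.date]:
    """Distinct resolved collection dates, strictly increasing."""
    return sorted({ev.resolved for ev in record.collection_events})


def segment_trips(dates: Sequence[dt.date],
                  gap_days: int = DEFAULT_GAP_DAYS) -> list[list[dt.date]]:
    """Group sorted distinct dates into field trips.

    Consecutive dates at most ``gap_days`` apart share a trip; a gap of
    strictly more than ``gap_days`` starts a new one ("more than one month").
    """
    dates = list(dates)
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("dates must be strictly increasing")
    trips: list[list[dt.date]] = []
    for d in dates:
        if trips and (d - trips[-1][-1]).days <= gap_days:
            trips[-1].append(d)
        else:
            trips.append([d])
    return trips


def compute_lags(record: TypeSeriesRecord,
                 gap_days: int = DEFAULT_GAP_DAYS) -> LagDecomposition:
    """Three lag periods plus unique-date and trip counts for one species."""
    dates = unique_sorted_dates(record)
    first, last = dates[0], dates[-1]
    pub = record.publication_date
    if pub <= last:
        raise ValueError(
            f"{record.species}: publication does not postdate last "
            "collection (should have been excluded upstream)")
    return LagDecomposition(
        species=record.species,
        region=record.region,
        genus=record.genus,
        overall_y=(pub - first).days / DAYS_PER_YEAR,
        collection_y=(last - first).days / DAYS_PER_YEAR,
        description_y=(pub - last).days / DAYS_PER_YEAR,
        n_unique_dates=len(dates),
        n_trips=len(segment_trips(dates, gap_days)),
    )


def lag_table(records: Iterable[TypeSeriesRecord],
              gap_days: int = DEFAULT_GAP_DAYS) -> pd.DataFrame:
    """Lag decomposition for every record, as a DataFrame."""
    rows = [compute_lags(r, gap_days) for r in records]
    return pd.DataFrame([{
        "species": l.species, "region": l.region, "genus": l.genus,
        "overall_y": l.overall_y, "collection_y": l.collection_y,
        "description_y": l.description_y,
        "n_unique_dates": l.n_unique_dates, "n_trips": l.n_trips,
    } for l in rows])


def cumulative_within(overall_lags: Sequence[float],
                      thresholds: Sequence[float]) -> list[float]:
    """Fraction of species described within each threshold (in years)."""
    lags = np.asarray(list(overall_lags), dtype=float)
    if lags.size == 0:
        raise ValueError("no lag values supplied")
    thr = list(thresholds)
    if any(b <= a for a, b in zip(thr, thr[1:])):
        raise ValueError("thresholds must be strictly increasing")
    return [float(np.mean(lags <= t)) for t in thr]


@dataclass
class SeasonalityMatrix:
    """Month x year grid of unique per-species collection-date counts."""
    region: str
    counts: pd.DataFrame  # index: month 1..12, columns: years

    def monthly_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_long(self) -> pd.DataFrame:
        long = (self.counts.stack().rename("count").reset_index())
        long.columns = ["month", "year", "count"]
        long.insert(0, "region", self.region)
        return long[["region", "year", "month", "count"]]


def seasonality_matrix(records: Iterable[TypeSeriesRecord],
                       region: str | None = None) -> SeasonalityMatrix:
    """Count unique per-species collection dates per (month, year).

    The same calendar date shared by two species counts twice (uniqueness
    is enforced within a species only).
    """
    dates: list[dt.date] = []
    label = region if region is not None else "global"
    for rec in records:
        if region is not None and rec.region != region:
            continue
        dates.extend(unique_sorted_dates(rec))
    if not dates:
        raise ValueError(f"no collection events for region {label!r}")
    years = sorted({d.year for d in dates})
    counts = pd.DataFrame(0, index=range(1, 13), columns=years, dtype=int)
    for d in dates:
        counts.loc[d.month, d.year] += 1
    counts.index.name = "month"
    counts.columns.name = "year"
    return SeasonalityMatrix(region=label, counts=counts)


def is_evenly_distributed(
    matrix: SeasonalityMatrix, min_fraction: float = 0.40,
) -> tuple[bool, pd.Series]:
    """Even-collection criterion: every month's pooled total must reach at
    least ``min_fraction`` of the peak month's total.  Returns the verdict
    and the per-month ratios to the peak."""
    totals = matrix.monthly_totals()
    peak = totals.max()
    if peak == 0:
        raise ValueError("all-zero seasonality matrix")
    ratios = totals / peak
    return bool((ratios >= min_fraction).all()), ratios
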