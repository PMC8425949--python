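"""Temporal trade dynamics: yearly series, effort-adjusted trend, lag analysis.

Raw yearly species counts from online detection confound trade intensity
with sampling effort (how many archived pages were retrieved each year), so
the trend is read from the residuals of an ordinary least squares regression
of species count on page count.  Separately, the lag between a species'
formal description and its first appearance in trade measures how quickly
newly described species are commercialised; species seen only in the
snapshot year carry no usable trade-onset date and are excluded from the
lag mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .webscan import DetectionRecord

__all__ = [
    "YearSeries",
    "TrendFit",
    "LagSummary",
    "yearly_series",
    "effort_adjusted_trend",
    "description_trade_lag",
]


@dataclass
class YearSeries:
    """Per-year species counts for one source, with page effort when known.

    ``n_species_unique_to_year`` counts species detected in that year and in
    no other year of the same source.
    """

    source: str
    table: pd.DataFrame  # columns: year, n_species, n_species_unique_to_year, n_pages


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of yearly species count on yearly page count."""

    intercept: float
    slope: float
    residuals: Mapping[int, float]
    degrees_of_freedom: int


@dataclass(frozen=True)
class LagSummary:
    """Description-to-trade lags for recently described species."""

    lags: Mapping[str, int]
    n_included: int
    n_excluded_snapshot_only: int
    mean_lag: float
    se_lag: float
    negative_lag_species: tuple[str, ...] = ()


def yearly_series(
    detections: Iterable[DetectionRecord] | Iterable[tuple[str, int]],
    pages_per_year: Mapping[int, int] | None = None,
    source: str = "online",
) -> YearSeries:
    """Tabulate species per year and species unique to a single year.

    ``detections`` may be DetectionRecords or bare ``(accepted_name, year)``
    pairs.  A species is counted once per year regardless of how many pages
    it appeared on.
    """
    species_years: dict[str, set[int]] = {}
    for det in detections:
        if isinstance(det, DetectionRecord):
            name, year = det.accepted_name, det.year
        else:
            name, year = det
        species_years.setdefault(name, set()).add(year)

    years: set[int] = set()
    for ys in species_years.values():
        years.update(ys)
    if pages_per_year:
        years.update(pages_per_year)

    rows = []
    for year in sorted(years):
        present = {sp for sp, ys in species_years.items() if year in ys}
        unique = {sp for sp in present if species_years[sp] == {year}}
        rows.append(
            {
                "year": year,
                "n_species": len(present),
                "n_species_unique_to_year": len(unique),
                "n_pages": int(pages_per_year.get(year, 0)) if pages_per_year else 0,
            }
        )
    table = pd.DataFrame(
        rows, columns=["year", "n_species", "n_species_unique_to_year", "n_pages"]
    )
    return YearSeries(source=source, table=table)


def effort_adjusted_trend(series: YearSeries) -> TrendFit:
    """OLS of yearly species count on yearly page count.

    The per-year residuals are the effort-adjusted trend signal; degrees of
    freedom = number of years - 2.
    """
    table = series.table
    if len(table) < 3:
        raise ValueError("effort-adjusted trend needs at least 3 years")
    y = table["n_species"].to_numpy(dtype=float)
    x = sm.add_constant(table["n_pages"].to_numpy(dtype=float))
    fit = sm.OLS(y, x).fit()
    residuals = {int(y): float(r) for y, r in zip(table["year"], fit.resid)}
    return TrendFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        residuals=residuals,
        degrees_of_freedom=int(fit.df_resid),
    )


def description_trade_lag(
    trade_years: Mapping[str, Collection[int]],
    year_described: Mapping[str, int],
    cutoff_year: int = 1999,
    snapshot_year: int = 2020,
) -> LagSummary:
    """Lag between species description and first appearance in trade.

    Candidates are species described after ``cutoff_year`` that appear in
    ``trade_years``.  A species whose only detection year is the snapshot
    year has no meaningful trade-onset date and is excluded (counted in
    ``n_excluded_snapshot_only``).  Lag = first trade year - description
    year; the summary reports the mean and its standard error (sample
    sd / sqrt(n)).  Negative lags (trade recorded before description) are
    retained but flagged as data errors.
    """
    lags: dict[str, int] = {}
    n_excluded = 0
    negative: list[str] = []
    for species in sorted(trade_years):
        described = year_described.get(species)
        if described is None or described <= cutoff_year:
            continue
        years = {int(y) for y in trade_years[species]}
        if not years:
            continue
        if years == {snapshot_year}:
            n_excluded += 1
            continue
        lag = min(years) - described
        lags[species] = lag
        if lag < 0:
            negative.append(species)

    n = len(lags)
    if n == 0:
        mean = se = float("nan")
    else:
        values = np.array(list(lags.values()), dtype=float)
        mean = float(values.mean())
        se = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return LagSummary(
        lags=lags,
        n_included=n,
        n_excluded_snapshot_only=n_excluded,
        mean_lag=mean,
        se_lag=se,
        negative_lag_species=tuple(negative),
    )
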