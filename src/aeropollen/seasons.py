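"""Annual Pollen Integral and Main Pollen Season statistics.

The Annual Pollen Integral (APIn, pollen·day/m^3) summarises a taxon's total
annual exposure: the mean observed daily concentration over the sampling
period multiplied by the period's calendar length (equal to the plain daily
sum when no days are missing).

The Main Pollen Season (MPS) is computed by the 90% method: the season
starts on the first day the cumulative annual sum reaches 5% of the annual
total and ends on the first day it reaches 95%.  This definition suits taxa
that pollinate very early in the year and clips trace concentrations
transported from outside the region.  A taxon is flagged *major* in a given
year when its APIn is at least 100 pollen·day/m^3.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TaxonSeries

logger = logging.getLogger(__name__)

#: Exported column set of the season-parameter table.
SEASON_TABLE_COLUMNS = [
    "Major Pollen",
    "Start Date",
    "End Date",
    "Duration of Season (Days)",
    "Max Daily Concentration (grains/m3)",
    "Day of Max Concentration",
    "APIn (Pollen * day/m3)",
    "% of Total Pollen",
]


@dataclass(frozen=True)
class SeasonMethodConfig:
    """Parameters of the 90% MPS method.

    lower_quantile / upper_quantile bound the cumulative-sum fractions that
    define season start and end (defaults 0.05 and 0.95, i.e. the central
    90%).  ``major_threshold`` is the APIn (pollen·day/m^3) at or above
    which a taxon counts as a major pollen type.  ``apin_mode`` selects how
    the APIn treats missing days: ``"mean_times_days"`` (mean of observed
    days scaled to the calendar length, the default) or ``"sum"`` (plain sum
    of observed days).
    """

    lower_quantile: float = 0.05
    upper_quantile: float = 0.95
    major_threshold: float = 100.0
    apin_mode: str = "mean_times_days"

    def __post_init__(self) -> None:
        if not 0 < self.lower_quantile < self.upper_quantile < 1:
            raise ValueError(
                "quantiles must satisfy 0 < lower < upper < 1, got "
                f"({self.lower_quantile}, {self.upper_quantile})"
            )
        if self.apin_mode not in ("mean_times_days", "sum"):
            raise ValueError(f"unknown apin_mode {self.apin_mode!r}")


@dataclass
class SeasonStats:
    """One row of the season-parameter table (one taxon, one year).

    ``duration_days`` is the calendar difference end − start.  ``defined``
    is False for years with zero annual total (no season can be assigned).
    ``quality_warning`` flags years where more than 25% of days are
    unobserved, e.g. a late monitoring start.
    """

    taxon: str
    year: int
    start_date: pd.Timestamp | None
    end_date: pd.Timestamp | None
    duration_days: int | None
    peak_date: pd.Timestamp | None
    peak_value: float
    apin: float
    pct_of_total: float
    is_major: bool
    n_missing_days: int = 0
    quality_warning: bool = False

    @property
    def defined(self) -> bool:
        return self.start_date is not None


def _year_frame(series: TaxonSeries, year: int) -> tuple[pd.Series, pd.Series]:
    """(values reindexed to the full year with NaN for missing, zero-filled)."""
    full = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    daily = series.year(year).reindex(full)
    return daily, daily.fillna(0.0)


def annual_pollen_integral(
    series: TaxonSeries,
    year: int | None = None,
    period: tuple | None = None,
    mode: str = "mean_times_days",
) -> float:
    """Annual Pollen Integral over a year or an explicit (start, end) period.

    ``mode="mean_times_days"`` multiplies the mean of the observed daily
    concentrations by the number of calendar days in the period, which
    equals the plain daily sum when no days are missing; ``mode="sum"``
    returns the plain sum of observed days.
    """
    if period is None:
        if year is None:
            raise ValueError("either year or period is required")
        start = pd.Timestamp(f"{year}-01-01")
        end = pd.Timestamp(f"{year}-12-31")
    else:
        start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    observed = series.values.loc[start:end].dropna()
    if observed.empty:
        raise ValueError(
            f"no observed days for {series.taxon} in {start.date()}..{end.date()}"
        )
    if mode == "sum":
        return float(observed.sum())
    if mode != "mean_times_days":
        raise ValueError(f"unknown mode {mode!r}")
    n_days = (end - start).days + 1
    return float(observed.mean() * n_days)


def main_pollen_season(
    series: TaxonSeries, year: int, cfg: SeasonMethodConfig = SeasonMethodConfig()
) -> SeasonStats:
    """Main Pollen Season of one taxon-year by the 90% (5%–95%) method.

    Start is the first date whose cumulative sum reaches
    ``lower_quantile × total``; end the first date reaching
    ``upper_quantile × total``.  Missing days contribute zero to the
    cumulative sum.  The peak is the earliest maximum inside [start, end].
    A zero annual total yields an undefined (flagged) season rather than an
    exception.
    """
    daily, filled = _year_frame(series, year)
    n_missing = int(daily.isna().sum())
    quality = n_missing > 0.25 * len(daily)
    if quality:
        logger.warning(
            "%s %d: %d of %d days unobserved; season statistics may be truncated",
            series.taxon, year, n_missing, len(daily),
        )
    total = float(filled.sum())
    if total <= 0:
        return SeasonStats(
            taxon=series.taxon, year=year, start_date=None, end_date=None,
            duration_days=None, peak_date=None, peak_value=0.0, apin=0.0,
            pct_of_total=float("nan"), is_major=False,
            n_missing_days=n_missing, quality_warning=quality,
        )
    cum = filled.cumsum().to_numpy()
    tol = 1e-12 * total  # guard float drift at exact quantile crossings
    start = filled.index[np.argmax(cum >= cfg.lower_quantile * total - tol)]
    end = filled.index[np.argmax(cum >= cfg.upper_quantile * total - tol)]
    window = filled.loc[start:end]
    peak_date = window.idxmax()  # idxmax → earliest date on ties
    apin = annual_pollen_integral(series, year=year, mode=cfg.apin_mode)
    return SeasonStats(
        taxon=series.taxon, year=year, start_date=start, end_date=end,
        duration_days=int((end - start).days), peak_date=peak_date,
        peak_value=float(window.max()), apin=apin, pct_of_total=float("nan"),
        is_major=apin >= cfg.major_threshold,
        n_missing_days=n_missing, quality_warning=quality,
    )


def total_series(series_list: list[TaxonSeries], site: str | None = None) -> TaxonSeries:
    """Daily sum over taxa ("Total" pollen); days unobserved for every taxon stay missing."""
    if not series_list:
        raise ValueError("need at least one taxon series")
    df = pd.DataFrame({s.taxon: s.values for s in series_list})
    tot = df.sum(axis=1, min_count=1)
    return TaxonSeries(site=site or series_list[0].site, taxon="Total", values=tot)


def season_table(
    series_list: list[TaxonSeries],
    year: int,
    cfg: SeasonMethodConfig = SeasonMethodConfig(),
) -> list[SeasonStats]:
    """Season-parameter rows for every taxon plus a "Total" row.

    ``pct_of_total`` is each taxon's APIn as a percentage of the summed
    APIn over all taxa (the Total row's denominator included).
    Rows are sorted by taxon name; Total comes last.
    """
    if not series_list:
        raise ValueError("need at least one taxon series")
    rows = [
        main_pollen_season(s, year, cfg)
        for s in sorted(series_list, key=lambda s: s.taxon)
    ]
    denom = sum(r.apin for r in rows if r.defined)
    for r in rows:
        if denom > 0 and r.defined:
            r.pct_of_total = 100.0 * r.apin / denom
    tot_row = main_pollen_season(total_series(series_list), year, cfg)
    if denom > 0 and tot_row.defined:
        tot_row.pct_of_total = 100.0 * tot_row.apin / denom
    rows.append(tot_row)
    return rows


def season_table_frame(rows: list[SeasonStats], date_format: str = "%d/%m/%Y") -> pd.DataFrame:
    """Format season rows as the printed table column set."""
    def fmt(d):
        return d.strftime(date_format) if d is not None else ""

    return pd.DataFrame(
        {
            "Major Pollen": [r.taxon for r in rows],
            "Start Date": [fmt(r.start_date) for r in rows],
            "End Date": [fmt(r.end_date) for r in rows],
            "Duration of Season (Days)": [
                r.duration_days if r.duration_days is not None else "" for r in rows
            ],
            "Max Daily Concentration (grains/m3)": [r.peak_value for r in rows],
            "Day of Max Concentration": [fmt(r.peak_date) for r in rows],
            "APIn (Pollen * day/m3)": [round(r.apin, 1) for r in rows],
            "% of Total Pollen": [
                round(r.pct_of_total, 1) if np.isfinite(r.pct_of_total) else ""
                for r in rows
            ],
        },
        columns=SEASON_TABLE_COLUMNS,
    )


def write_season_table(rows: list[SeasonStats], path) -> None:
    season_table_frame(rows).to_csv(path, index=False)
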