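"""Reading, writing and basic derivation of pollen and meteorology tables.

Daily pollen concentrations (grains/m^3) and daily meteorological records are
the two inputs every downstream stage consumes.  Concentrations come from
Hirst-type volumetric traps: air is drawn at a known flow rate onto an
adhesive tape, a fixed fraction of each daily slide is counted under the
microscope, and the raw grain count is scaled to the whole slide and divided
by the sampled air volume.

Missing days are first-class: they are stored as absent dates (or NaN) and
are never silently imputed at ingestion.  Downstream stages decide how to
treat them.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: kilometres per hour in one knot (wind speeds are archived in knots).
KNOT_TO_KMH = 1.852

#: Daily meteorological parameter abbreviations accepted by the readers.
#: Tmean/Tmax/Tmin in deg C, Gmin = grass minimum temperature (2 cm), Soil =
#: 10 cm soil temperature, Rain in mm, Cbl = mean CBL pressure (hPa), Wind_s
#: in knots, Wind_d in degrees, G_rad in J/cm^2, Pe/Evap in mm, Rh in %,
#: Sun in hours.  Derived "_10" columns are 10-day trailing means.
METEO_PARAMS = (
    "Tmean", "Tmax", "Tmin", "Gmin", "Soil", "Rain", "Cbl",
    "Wind_s", "Wind_d", "G_rad", "Pe", "Evap", "Rh", "Sun",
)


@dataclass(frozen=True)
class TrapConfig:
    """Volumetric-trap geometry used to convert raw counts to concentrations.

    Parameters
    ----------
    flow_rate : float
        Air intake, litres per minute (the Hirst standard is 10 L/min).
    counted_fraction : float
        Fraction of the daily slide surface actually counted, in (0, 1].
        Four horizontal transects correspond to roughly 12-13% of the
        surface; the default is the midpoint, 0.125.
    sampling_minutes : float
        Minutes of air sampling represented by one slide (1440 for a daily
        slide).
    """

    flow_rate: float = 10.0
    counted_fraction: float = 0.125
    sampling_minutes: float = 1440.0

    def __post_init__(self) -> None:
        if not self.flow_rate > 0:
            raise ValueError(f"flow_rate must be > 0, got {self.flow_rate}")
        if not 0 < self.counted_fraction <= 1:
            raise ValueError(
                f"counted_fraction must be in (0, 1], got {self.counted_fraction}"
            )
        if not self.sampling_minutes > 0:
            raise ValueError(
                f"sampling_minutes must be > 0, got {self.sampling_minutes}"
            )

    @property
    def sampled_volume_m3(self) -> float:
        """Air volume sampled per slide, cubic metres."""
        return self.flow_rate * self.sampling_minutes / 1000.0


def raw_count_to_concentration(count, cfg: TrapConfig = TrapConfig()):
    """Convert a raw counted number of grains to a concentration in grains/m^3.

    The count from the examined transects is scaled up to the whole slide
    (division by ``counted_fraction``) and divided by the air volume sampled
    over the slide's duration.

    Accepts scalars or array-likes; negative counts are rejected.
    """
    arr = np.asarray(count, dtype=float)
    if np.any(arr < 0):
        raise ValueError("raw pollen count must be non-negative")
    out = arr / cfg.counted_fraction / cfg.sampled_volume_m3
    if np.isscalar(count) or arr.ndim == 0:
        return float(out)
    return out


def _validate_daily_index(values: pd.Series, what: str) -> pd.Series:
    if not isinstance(values.index, pd.DatetimeIndex):
        values = values.copy()
        values.index = pd.DatetimeIndex(values.index)
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique()
        raise ValueError(f"duplicate dates in {what}: {list(dupes[:5])}")
    values = values.sort_index()
    values.index = values.index.normalize()
    finite = values.dropna()
    if (finite < 0).any():
        bad = finite.index[finite < 0]
        raise ValueError(f"negative concentrations in {what} at {list(bad[:5])}")
    return values.astype(float)


@dataclass
class TaxonSeries:
    """Daily pollen concentration for one taxon at one site.

    ``values`` is a date-indexed :class:`pandas.Series` in grains/m^3.
    Absent dates and NaN entries both denote missing days and are distinct
    from zero concentration.
    """

    site: str
    taxon: str
    values: pd.Series

    def __post_init__(self) -> None:
        self.values = _validate_daily_index(self.values, f"{self.taxon}@{self.site}")
        self.values.name = self.taxon

    def year(self, year: int) -> pd.Series:
        """Observed values within one calendar year (missing days absent)."""
        return self.values[self.values.index.year == year]

    @property
    def years(self) -> list[int]:
        return sorted(set(self.values.dropna().index.year))


@dataclass
class HourlySeries:
    """Hour-resolution pollen concentration for one taxon at one site."""

    site: str
    taxon: str
    values: pd.Series

    def __post_init__(self) -> None:
        values = self.values
        if not isinstance(values.index, pd.DatetimeIndex):
            values = values.copy()
            values.index = pd.DatetimeIndex(values.index)
        if values.index.has_duplicates:
            raise ValueError(f"duplicate timestamps for {self.taxon}@{self.site}")
        if ((values.index.minute != 0) | (values.index.second != 0)).any():
            raise ValueError("hourly series timestamps must be hour-aligned")
        finite = values.dropna()
        if (finite < 0).any():
            raise ValueError("negative hourly concentrations")
        self.values = values.sort_index().astype(float)
        self.values.name = self.taxon


@dataclass
class MeteoSeries:
    """Daily meteorological record for one site (subset of METEO_PARAMS)."""

    site: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            df = df.copy()
            df.index = pd.DatetimeIndex(df.index)
        if df.index.has_duplicates:
            raise ValueError(f"duplicate dates in meteorology for {self.site}")
        df = df.sort_index()
        df.index = df.index.normalize()
        if "Rh" in df:
            rh = df["Rh"].dropna()
            if ((rh < 0) | (rh > 100)).any():
                raise ValueError("Rh must lie in [0, 100] %")
        if "Wind_d" in df:
            wd = df["Wind_d"].dropna()
            if ((wd < 0) | (wd >= 360)).any():
                raise ValueError("Wind_d must lie in [0, 360) degrees")
        if "Rain" in df:
            rain = df["Rain"].dropna()
            if (rain < 0).any():
                raise ValueError("Rain must be non-negative")
        self.data = df.astype(float)

    @property
    def params(self) -> list[str]:
        return list(self.data.columns)


def _parse_dates(raw: pd.Series, dayfirst: bool, path) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, dayfirst=dayfirst, errors="coerce", format="mixed")
    if parsed.isna().any():
        bad_rows = [int(i) + 2 for i in np.flatnonzero(parsed.isna().to_numpy())[:10]]
        raise ValueError(
            f"{path}: unparsable dates at file rows {bad_rows} (1-based, incl. header)"
        )
    return pd.DatetimeIndex(parsed)


def read_pollen_table(
    path,
    layout: str = "wide",
    site: str = "",
    dayfirst: bool = True,
    date_column: str | None = None,
    sep: str = ",",
) -> list[TaxonSeries]:
    """Read a delimited pollen table into one :class:`TaxonSeries` per taxon.

    ``layout="wide"`` expects a date column plus one column per taxon;
    ``layout="long"`` expects columns (date, taxon, value).  Unparsable
    dates, duplicate (date, taxon) pairs and negative values are rejected
    with the offending rows named.  Empty tables yield an empty list with a
    logged warning.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty pollen table, returning no series", path)
        return []
    if df.empty:
        logger.warning("%s: pollen table has no rows, returning no series", path)
        return []
    date_col = date_column or df.columns[0]
    dates = _parse_dates(df[date_col], dayfirst, path)

    out: list[TaxonSeries] = []
    if layout == "wide":
        for col in df.columns:
            if col == date_col:
                continue
            vals = pd.to_numeric(df[col], errors="raise")
            if (vals.dropna() < 0).any():
                bad = [int(i) + 2 for i in np.flatnonzero((vals < 0).to_numpy())[:10]]
                raise ValueError(
                    f"{path}: negative concentration for {col!r} at file rows {bad}"
                )
            series = pd.Series(vals.to_numpy(), index=dates)
            if series.index.has_duplicates:
                dupes = series.index[series.index.duplicated()].unique()
                raise ValueError(
                    f"{path}: duplicate dates {[str(d.date()) for d in dupes[:5]]} "
                    f"for taxon {col!r}"
                )
            out.append(TaxonSeries(site=site, taxon=str(col), values=series))
    else:
        cols = list(df.columns)
        if len(cols) < 3:
            raise ValueError(f"{path}: long layout needs (date, taxon, value) columns")
        taxon_col, value_col = cols[1], cols[2]
        vals = pd.to_numeric(df[value_col], errors="raise")
        if (vals.dropna() < 0).any():
            bad = [int(i) + 2 for i in np.flatnonzero((vals < 0).to_numpy())[:10]]
            raise ValueError(f"{path}: negative concentration at file rows {bad}")
        key = pd.MultiIndex.from_arrays([dates, df[taxon_col]])
        if key.duplicated().any():
            dupes = key[key.duplicated()][:5].tolist()
            raise ValueError(f"{path}: duplicate (date, taxon) pairs: {dupes}")
        for taxon, grp in df.assign(_date=dates).groupby(taxon_col, sort=True):
            series = pd.Series(
                pd.to_numeric(grp[value_col]).to_numpy(),
                index=pd.DatetimeIndex(grp["_date"]),
            )
            out.append(TaxonSeries(site=site, taxon=str(taxon), values=series))
    return out


def write_pollen_table(series_list: list[TaxonSeries], path, layout: str = "wide") -> None:
    """Write TaxonSeries back to delimited text (inverse of read_pollen_table)."""
    if layout == "wide":
        df = pd.DataFrame({s.taxon: s.values for s in series_list})
        df.index.name = "date"
        df.to_csv(path, date_format="%Y-%m-%d")
    elif layout == "long":
        rows = []
        for s in series_list:
            for date, val in s.values.items():
                rows.append((date.strftime("%Y-%m-%d"), s.taxon, val))
        pd.DataFrame(rows, columns=["date", "taxon", "value"]).to_csv(path, index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def read_hourly_table(
    path, site: str = "", dayfirst: bool = True, sep: str = ","
) -> list[HourlySeries]:
    """Read a wide hourly pollen table (timestamp column + one column per taxon)."""
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        logger.warning("%s: empty hourly table", path)
        return []
    ts_col = df.columns[0]
    stamps = pd.DatetimeIndex(
        pd.to_datetime(df[ts_col], dayfirst=dayfirst, format="mixed")
    )
    return [
        HourlySeries(site=site, taxon=str(c),
                     values=pd.Series(pd.to_numeric(df[c]).to_numpy(), index=stamps))
        for c in df.columns if c != ts_col
    ]


def read_meteo_table(path, site: str = "", dayfirst: bool = True, sep: str = ",") -> MeteoSeries:
    """Read a daily meteorology table (date column + named parameter columns)."""
    df = pd.read_csv(path, sep=sep)
    date_col = df.columns[0]
    dates = _parse_dates(df[date_col], dayfirst, path)
    data = df.drop(columns=[date_col])
    data.index = dates
    return MeteoSeries(site=site, data=data)


def lagged_mean(
    met: MeteoSeries,
    param: str,
    window_days: int = 10,
    min_periods: int | None = None,
) -> pd.Series:
    """Trailing mean of a meteorological parameter over the previous N days.

    The value at date *d* is the mean of ``param`` over the ``window_days``
    calendar dates strictly preceding *d* (the current day is excluded, so
    the derived series is usable as a lag predictor).  The mean is reported
    as missing when fewer than ``min_periods`` observations fall in the
    window; the default threshold is ``ceil(window_days / 2)``.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if param not in met.data.columns:
        raise KeyError(
            f"unknown parameter {param!r}; available: {sorted(met.data.columns)}"
        )
    if min_periods is None:
        min_periods = math.ceil(window_days / 2)
    full = pd.date_range(met.data.index.min(), met.data.index.max(), freq="D")
    daily = met.data[param].reindex(full)
    out = daily.shift(1).rolling(window=window_days, min_periods=min_periods).mean()
    out.name = f"{param}_{window_days}"
    return out


def add_lagged_means(
    met: MeteoSeries, params: list[str] | None = None, window_days: int = 10
) -> MeteoSeries:
    """Return a MeteoSeries extended with ``<param>_<window>`` trailing means.

    By default the temperature and rain lags used in season screening
    (Tmean_10, Rain_10) are added when the base columns exist.
    """
    if params is None:
        params = [p for p in ("Tmean", "Rain") if p in met.data.columns]
    extra = {}
    for p in params:
        lag = lagged_mean(met, p, window_days)
        extra[lag.name] = lag.reindex(met.data.index)
    data = met.data.copy()
    for name, col in extra.items():
        data[name] = col
    return MeteoSeries(site=met.site, data=data)
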