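"""Multi-year pollen calendar construction.

A pollen calendar summarises the average annual rhythm of each taxon at a
site.  Daily concentrations are first averaged across years into a daily
climatology; each month is then divided into five sections (days 1-6, 7-12,
13-18, 19-24 and 25-end, so the last section absorbs the month remainder)
and the mean of each section is displayed.  Flowering periods are read off
the climatology's cumulative curve: the main flowering period is the
10%-90% interval of the annual integral, early/late flank it between the
0.5% and 99.5% points, and any day with pollen outside the 0.5%-99.5% range
counts as possible occurrence.  Cells are finally coloured by an
allergenicity class (high / moderate / low) supplied as user configuration,
since allergenic potential is a literature judgement, not a property of the
counts.
"""
from __future__ import annotations

import calendar as _stdcal
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TaxonSeries

#: ranking used when a section spans several flowering-period classes
PERIOD_RANK = {"none": 0, "possible": 1, "early": 2, "late": 3, "main": 4}

ALLERGENICITY_CLASSES = ("high", "moderate", "low")

#: Editable default allergenicity table for common NW-European taxa
#: (literature-style assignment; override via build_calendar's config).
DEFAULT_ALLERGENICITY = {
    "Poaceae": "high",
    "Betula": "high",
    "Alnus": "high",
    "Corylus": "high",
    "Urticaceae": "moderate",
    "Fraxinus": "moderate",
    "Plantago": "moderate",
    "Quercus": "moderate",
    "Rumex": "moderate",
    "Pinus": "low",
    "Cupressaceae/Taxaceae": "low",
    "Salix": "low",
    "Ulmus": "low",
    "Platanus": "low",
    "Castanea": "low",
    "Fagus": "low",
    "Ericaceae": "low",
    "Carpinus": "moderate",
}


def _month_day_index() -> pd.MultiIndex:
    """(month, day) pairs for all 366 possible calendar days, in year order."""
    pairs = []
    for month in range(1, 13):
        ndays = 29 if month == 2 else _stdcal.monthrange(2001, month)[1]
        pairs.extend((month, d) for d in range(1, ndays + 1))
    return pd.MultiIndex.from_tuples(pairs, names=["month", "day"])


@dataclass
class DailyClimatology:
    """Mean concentration per calendar day across years, for one taxon.

    ``values`` and ``n_years`` are indexed by (month, day) over all 366
    possible days; days never observed are NaN (with n_years 0).  Feb 29
    is averaged only over the leap years that supply it.
    """

    taxon: str
    values: pd.Series
    n_years: pd.Series

    @property
    def annual_mean(self) -> float:
        """Mean over the days with a defined climatology value."""
        return float(self.values.dropna().mean())

    @property
    def annual_total(self) -> float:
        return float(self.values.dropna().sum())


def daily_climatology(series_list: list[TaxonSeries], taxon: str) -> DailyClimatology:
    """Average daily concentrations across years for one taxon.

    Accepts any mix of single-year and multi-year series; a year missing a
    given calendar day simply does not contribute to that day's mean.
    """
    own = [s for s in series_list if s.taxon == taxon]
    if not own:
        raise ValueError(f"no series for taxon {taxon!r}")
    merged = pd.concat([s.values for s in own])
    if merged.index.has_duplicates:
        raise ValueError(f"overlapping dates across series for {taxon!r}")
    merged = merged.dropna()
    grouped = merged.groupby([merged.index.month, merged.index.day])
    idx = _month_day_index()
    values = grouped.mean().reindex(idx)
    n_years = grouped.count().reindex(idx).fillna(0).astype(int)
    return DailyClimatology(taxon=taxon, values=values, n_years=n_years)


def partition_sections(clim: DailyClimatology) -> pd.DataFrame:
    """Mean concentration of the 60 month-sections (5 per month).

    Sections 1-4 cover days 1-6, 7-12, 13-18, 19-24; section 5 runs from
    day 25 to the month's end (4-7 days).  The section mean averages the
    days with a defined climatology value; ``n_days`` records how many
    contributed (the weight needed to reconstruct the annual mean).
    """
    rows = []
    for month in range(1, 13):
        ndays = 29 if month == 2 else _stdcal.monthrange(2001, month)[1]
        for section in range(1, 6):
            lo = 6 * (section - 1) + 1
            hi = 6 * section if section < 5 else ndays
            days = clim.values.loc[(month, slice(lo, hi))]
            defined = days.dropna()
            rows.append(
                {
                    "month": month,
                    "section": section,
                    "mean_concentration": float(defined.mean()) if len(defined) else np.nan,
                    "n_days": int(len(defined)),
                }
            )
    return pd.DataFrame(rows)


def flowering_periods(clim: DailyClimatology) -> pd.Series:
    """Classify every calendar day of the climatology into a flowering period.

    With F(d) the cumulative fraction of the annual integral up to and
    including day d (missing days contributing zero):

    * main  — from the first day F reaches 10% through the first day F
      reaches 90% (both inclusive);
    * early — days before the main period with F(d) > 0.5%;
    * late  — days after the main period with F(d) < 99.5%;
    * possible — any other day on which pollen occurs (climatology > 0);
    * none  — everything else.

    A zero-total climatology classifies every day as none.
    """
    filled = clim.values.fillna(0.0)
    total = float(filled.sum())
    classes = pd.Series("none", index=clim.values.index, dtype=object)
    if total <= 0:
        return classes
    frac = filled.cumsum().to_numpy() / total
    tol = 1e-12  # guard float drift at exact fraction crossings
    start_main = int(np.argmax(frac >= 0.10 - tol))
    end_main = int(np.argmax(frac >= 0.90 - tol))
    pos = np.arange(len(frac))
    vals = filled.to_numpy()
    main = (pos >= start_main) & (pos <= end_main)
    early = (pos < start_main) & (frac > 0.005)
    late = (pos > end_main) & (frac < 0.995)
    possible = ~(main | early | late) & (vals > 0)
    classes[main] = "main"
    classes[early] = "early"
    classes[late] = "late"
    classes[possible] = "possible"
    return classes


@dataclass
class PollenCalendar:
    """Calendar cells for a set of taxa: 60 sections each, Jan-s1 … Dec-s5.

    ``cells`` columns: taxon, month, section, mean_concentration,
    period_class, allergenicity.
    """

    cells: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return list(pd.unique(self.cells["taxon"]))

    def for_taxon(self, taxon: str) -> pd.DataFrame:
        return self.cells[self.cells["taxon"] == taxon].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def build_calendar(
    climatologies: list[DailyClimatology],
    allergenicity: dict[str, str] | None = None,
) -> PollenCalendar:
    """Assemble the pollen calendar from per-taxon climatologies.

    Each cell carries its section mean and the highest-ranking flowering
    class among its days (main > late > early > possible > none), so a
    section containing any main-period day displays as main.  Every taxon
    must have an allergenicity entry.
    """
    config = DEFAULT_ALLERGENICITY if allergenicity is None else allergenicity
    missing = [c.taxon for c in climatologies if c.taxon not in config]
    if missing:
        raise KeyError(f"taxa missing from allergenicity config: {sorted(missing)}")
    bad = {t: v for t, v in config.items() if v not in ALLERGENICITY_CLASSES}
    if bad:
        raise ValueError(f"invalid allergenicity classes: {bad}")

    frames = []
    for clim in climatologies:
        sections = partition_sections(clim)
        day_class = flowering_periods(clim)
        cell_classes = []
        for _, row in sections.iterrows():
            month, section = int(row["month"]), int(row["section"])
            ndays = 29 if month == 2 else _stdcal.monthrange(2001, month)[1]
            lo = 6 * (section - 1) + 1
            hi = 6 * section if section < 5 else ndays
            classes = day_class.loc[(month, slice(lo, hi))]
            cell_classes.append(max(classes, key=PERIOD_RANK.__getitem__))
        sections = sections.assign(
            taxon=clim.taxon,
            period_class=cell_classes,
            allergenicity=config[clim.taxon],
        )
        frames.append(sections)
    cells = pd.concat(frames, ignore_index=True)[
        ["taxon", "month", "section", "mean_concentration", "n_days",
         "period_class", "allergenicity"]
    ]
    return PollenCalendar(cells=cells)


def plot_calendar(cal: PollenCalendar, path) -> None:
    """Render the calendar as taxa rows × 60 section columns.

    Cell colour encodes allergenicity (red/orange/green for high/moderate/
    low); shading intensity encodes the flowering-period class.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colors as mcolors
    from matplotlib.patches import Rectangle

    base = {"high": "#c0392b", "moderate": "#e67e22", "low": "#27ae60"}
    alpha = {"none": 0.0, "possible": 0.2, "early": 0.45, "late": 0.45, "main": 1.0}
    taxa = cal.taxa
    fig, ax = plt.subplots(figsize=(12, 0.4 * len(taxa) + 1.5))
    for i, taxon in enumerate(taxa):
        sub = cal.for_taxon(taxon)
        for _, row in sub.iterrows():
            col = 5 * (int(row["month"]) - 1) + int(row["section"]) - 1
            rgba = mcolors.to_rgba(base[row["allergenicity"]],
                                   alpha[row["period_class"]])
            ax.add_patch(Rectangle((col, len(taxa) - 1 - i), 1, 1,
                                   facecolor=rgba, edgecolor="0.85", lw=0.3))
    ax.set_xlim(0, 60)
    ax.set_ylim(0, len(taxa))
    ax.set_yticks([len(taxa) - 1 - i + 0.5 for i in range(len(taxa))])
    ax.set_yticklabels(taxa, fontsize=8)
    ax.set_xticks([5 * m + 2.5 for m in range(12)])
    ax.set_xticklabels([_stdcal.month_abbr[m + 1] for m in range(12)])
    ax.set_title("Pollen calendar")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
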