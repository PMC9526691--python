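"""Average diurnal (hour-of-day) pollen profiles.

Hourly concentrations are averaged over the days of a period to show when
in the day a taxon's pollen peaks.  Two modes are supported: *absolute*
(mean concentration per hour) and *percent* (each day first converted to
percent of its own daily total, so day-to-day abundance swings do not
drown the diurnal shape; days with zero total are excluded).  Percent is
the default.  Peak windows — possibly more than one for bimodal profiles —
are the maximal contiguous hour ranges at or above a fraction of the
profile maximum, with wrap-around across midnight handled.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HourlySeries


@dataclass
class DiurnalProfile:
    """24 mean values by hour of day, plus how many days contributed."""

    label: str
    values: np.ndarray  # shape (24,)
    mode: str  # "absolute" | "percent"
    n_days: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (24,):
            raise ValueError("profile must have exactly 24 hourly values")

    def to_frame(self) -> pd.DataFrame:
        unit = "%" if self.mode == "percent" else "grains/m3"
        return pd.DataFrame(
            {"hour": np.arange(24), f"mean ({unit})": self.values}
        )


def mean_hourly_profile(
    hourly: HourlySeries,
    period: tuple | None = None,
    mode: str = "percent",
    min_hours: int = 12,
) -> DiurnalProfile:
    """Average hourly distribution over the days of a period.

    A day qualifies when at least ``min_hours`` of its hours are observed.
    In percent mode each qualifying day with a positive total is rescaled
    to percent of that total before averaging, so the returned profile sums
    to 100; in absolute mode hours are averaged directly (missing hours
    ignored per hour).
    """
    if mode not in ("absolute", "percent"):
        raise ValueError(f"mode must be 'absolute' or 'percent', got {mode!r}")
    values = hourly.values
    if period is not None:
        start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
        values = values.loc[start: end + pd.Timedelta(hours=23)]
    if values.dropna().empty:
        raise ValueError("no observed hours in period")
    frame = values.to_frame("conc")
    frame["date"] = frame.index.normalize()
    frame["hour"] = frame.index.hour
    table = frame.pivot(index="date", columns="hour", values="conc")
    table = table.reindex(columns=np.arange(24))
    qualifying = table.notna().sum(axis=1) >= min_hours
    table = table[qualifying]
    if table.empty:
        raise ValueError(
            f"no days with >= {min_hours} observed hours in period"
        )
    if mode == "absolute":
        profile = table.mean(axis=0)
        n_days = int(len(table))
    else:
        totals = table.sum(axis=1, skipna=True)
        positive = totals > 0
        table = table[positive]
        if table.empty:
            raise ValueError("no days with positive totals for percent mode")
        pct = table.div(table.sum(axis=1), axis=0) * 100.0
        profile = pct.mean(axis=0)
        n_days = int(len(table))
    return DiurnalProfile(
        label=hourly.taxon,
        values=profile.to_numpy(),
        mode=mode,
        n_days=n_days,
    )


def peak_window(profile: DiurnalProfile, frac: float = 0.8) -> list[tuple[int, int]]:
    """Maximal contiguous hour ranges where the profile >= frac * maximum.

    Returns inclusive (start_hour, end_hour) tuples; a range crossing
    midnight is reported as e.g. (22, 2).  A flat profile yields the single
    window (0, 23).  Ranges are ordered by start hour.
    """
    vals = profile.values
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("profile has no finite values")
    mask = np.where(np.isfinite(vals), vals >= frac * finite.max(), False)
    if mask.all():
        return [(0, 23)]
    # find runs on the circle: break at a False position
    breaks = np.flatnonzero(~mask)
    windows: list[tuple[int, int]] = []
    start = None
    for h in range(breaks[0], breaks[0] + 24):
        idx = h % 24
        if mask[idx] and start is None:
            start = idx
        elif not mask[idx] and start is not None:
            windows.append((start, (idx - 1) % 24))
            start = None
    if start is not None:
        windows.append((start, (breaks[0] - 1) % 24))
    windows.sort(key=lambda w: w[0])
    return windows


def plot_profile(profiles: list[DiurnalProfile], path) -> None:
    """Line plot of one or more diurnal profiles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for p in profiles:
        ax.plot(np.arange(24), p.values, marker="o", ms=3, label=p.label)
    ax.set_xlabel("hour of day")
    ax.set_ylabel("% of daily total" if profiles and profiles[0].mode == "percent"
                  else "grains/m$^3$")
    ax.set_xticks(range(0, 24, 2))
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
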