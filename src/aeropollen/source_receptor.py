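"""Source-receptor analysis of airborne pollen from wind records.

Given daily pollen concentrations paired with wind speed/direction
observations, these tools estimate where the pollen comes from:

* :func:`yamartino_sigma` — single-pass estimator of the circular standard
  deviation of wind direction, bounded above by about 103.9 degrees;
* :class:`NonparametricWindRegression` (NWR) — kernel-smoothed expected
  concentration on a polar (direction x speed) grid;
* :class:`SustainedWindIncidence` (SWIM) — the NWR variant that up-weights
  observations with low direction variability by the factor
  sigma_mean / sigma_i, so sustained winds dominate the estimate;
* :func:`joint_probability_rose` — the polar histogram of wind occurrence;
* :func:`dominant_sector` — compass sector and speed band of a grid maximum.

Directions follow the meteorological convention throughout: degrees the
wind blows FROM, 0 = North, increasing clockwise.  All angular arithmetic
is wrapped on the circle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .io import KNOT_TO_KMH

logger = logging.getLogger(__name__)

#: Upper bound of the Yamartino estimator: 90 * 2/sqrt(3) degrees.
SIGMA_MAX_DEG = 90.0 * 2.0 / np.sqrt(3.0)

SECTOR_LABELS_8 = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
SECTOR_LABELS_16 = (
    "N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
    "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW",
)

#: Speed-ring edges (km/h) used on the printed roses.
DEFAULT_SPEED_RINGS = (0.0, 2.0, 4.0, 8.0, 12.0)


@dataclass(frozen=True)
class WindObservation:
    """One wind record: timestamp, speed (km/h), direction (deg from),
    and optionally the Yamartino direction standard deviation (deg) of the
    averaging period."""

    when: pd.Timestamp
    speed: float
    direction: float
    sigma_dir: float | None = None

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("wind speed must be >= 0")
        if not 0 <= self.direction < 360:
            raise ValueError("wind direction must lie in [0, 360)")
        if self.sigma_dir is not None and not 0 <= self.sigma_dir <= SIGMA_MAX_DEG + 1e-9:
            raise ValueError(
                f"sigma_dir must lie in [0, {SIGMA_MAX_DEG:.2f}], got {self.sigma_dir}"
            )


def angular_distance(a, b):
    """Smallest absolute angle between two directions, degrees in [0, 180]."""
    return np.abs((np.asarray(a, float) - np.asarray(b, float) + 180.0) % 360.0 - 180.0)


def yamartino_sigma(directions) -> float:
    """Single-pass Yamartino estimate of the direction standard deviation.

    With s = mean(sin θ), c = mean(cos θ) and ε = sqrt(1 − (s² + c²)),
    the estimate is asin(ε)·(1 + (2/√3 − 1)·ε³), returned in degrees.
    It is exact at zero spread and reaches its maximum of ≈103.92° for
    directions uniform on the circle.
    """
    arr = np.asarray(directions, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one direction")
    rad = np.deg2rad(arr)
    s, c = np.mean(np.sin(rad)), np.mean(np.cos(rad))
    eps2 = 1.0 - (s * s + c * c)
    eps = np.sqrt(max(eps2, 0.0))  # guard tiny negative from rounding
    sigma = np.arcsin(min(eps, 1.0)) * (1.0 + (2.0 / np.sqrt(3.0) - 1.0) * eps**3)
    return float(np.rad2deg(sigma))


def circular_sd(directions) -> float:
    """Two-pass circular standard deviation (degrees); reference for sigma."""
    rad = np.deg2rad(np.asarray(directions, dtype=float))
    R = np.hypot(np.mean(np.sin(rad)), np.mean(np.cos(rad)))
    R = min(max(R, 1e-300), 1.0)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(R))))


@dataclass
class PolarGrid:
    """Direction × speed grid of concentration estimates or probabilities.

    ``direction_edges`` has n+1 entries tiling [0, 360]; ``speed_edges``
    m+1 entries; ``values`` is (n, m) with NaN marking undefined cells.
    ``kind`` is "concentration" or "probability".
    """

    direction_edges: np.ndarray
    speed_edges: np.ndarray
    values: np.ndarray
    kind: str = "concentration"

    def __post_init__(self) -> None:
        self.direction_edges = np.asarray(self.direction_edges, float)
        self.speed_edges = np.asarray(self.speed_edges, float)
        self.values = np.asarray(self.values, float)
        n, m = len(self.direction_edges) - 1, len(self.speed_edges) - 1
        if self.values.shape != (n, m):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {m})")

    @property
    def direction_centers(self) -> np.ndarray:
        return (self.direction_edges[:-1] + self.direction_edges[1:]) / 2.0 % 360.0

    @property
    def speed_centers(self) -> np.ndarray:
        return (self.speed_edges[:-1] + self.speed_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(np.round(self.direction_centers, 3), name="direction_deg"),
            columns=pd.Index(np.round(self.speed_centers, 3), name="speed_kmh"),
        )
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _as_wind_frame(wind) -> pd.DataFrame:
    """Normalise wind input (list of WindObservation or DataFrame) to a frame."""
    if isinstance(wind, pd.DataFrame):
        df = wind.copy()
        required = {"speed", "direction"}
        if not required <= set(df.columns):
            raise ValueError(f"wind frame needs columns {sorted(required)}")
        return df
    rows = [
        {"when": w.when, "speed": w.speed, "direction": w.direction,
         "sigma_dir": w.sigma_dir}
        for w in wind
    ]
    if not rows:
        raise ValueError("need at least one wind observation")
    return pd.DataFrame(rows).set_index("when")


class NonparametricWindRegression(RegressorMixin, BaseEstimator):
    """Kernel-smoothed concentration as a function of wind direction and speed.

    The estimate at a polar point (θ, v) is the weighted mean of the
    observed concentrations, each observation weighted by the product of a
    wrapped Gaussian kernel in direction (bandwidth ``direction_bandwidth``
    degrees, on angular distance) and a Gaussian kernel in speed (bandwidth
    ``speed_bandwidth`` km/h).  Grid cells whose total kernel weight falls
    below ``weight_floor`` are left undefined (NaN).

    Parameters
    ----------
    direction_bandwidth : float, default 15.0
        Gaussian kernel width in direction, degrees.
    speed_bandwidth : float, default 2.0
        Gaussian kernel width in speed, km/h.
    n_direction_bins : int, default 72
        Number of direction bins of the fitted grid (5° at the default).
    speed_step : float, default 0.5
        Speed resolution of the fitted grid, km/h.
    max_speed : float or None
        Upper speed edge of the grid; the observed maximum when None.
    weight_floor : float, default 1e-3
        Minimum total kernel weight for a cell to be defined.

    Attributes
    ----------
    grid_ : PolarGrid
        Fitted polar concentration surface.
    X_, y_ : ndarray
        Stored training observations.
    """

    def __init__(
        self,
        direction_bandwidth: float = 15.0,
        speed_bandwidth: float = 2.0,
        n_direction_bins: int = 72,
        speed_step: float = 0.5,
        max_speed: float | None = None,
        weight_floor: float = 1e-3,
    ):
        self.direction_bandwidth = direction_bandwidth
        self.speed_bandwidth = speed_bandwidth
        self.n_direction_bins = n_direction_bins
        self.speed_step = speed_step
        self.max_speed = max_speed
        self.weight_floor = weight_floor

    # -- weighting ---------------------------------------------------------
    def _observation_weights(self, X: np.ndarray) -> np.ndarray:
        """Per-observation multiplicative weights (1 for plain NWR)."""
        return np.ones(len(X))

    def _kernel_matrix(self, dirs, speeds) -> np.ndarray:
        """(n_points, n_obs) kernel weights, including observation weights."""
        if self.direction_bandwidth <= 0 or self.speed_bandwidth <= 0:
            raise ValueError("kernel bandwidths must be positive")
        dd = angular_distance(dirs[:, None], self.X_[None, :, 0])
        dv = speeds[:, None] - self.X_[None, :, 1]
        w = np.exp(-0.5 * (dd / self.direction_bandwidth) ** 2)
        w *= np.exp(-0.5 * (dv / self.speed_bandwidth) ** 2)
        return w * self.obs_weights_[None, :]

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        """Fit the polar surface.

        X : array (n, 2) of [direction_deg, speed_kmh] (SWIM expects a third
        sigma column); y : concentrations (grains/m^3).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be (n, >=2): [direction, speed(, sigma)]")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) == 0:
            raise ValueError("need at least one (wind, concentration) pair")
        keep = ~(np.isnan(y) | np.isnan(X[:, :2]).any(axis=1))
        X, y = X[keep], y[keep]
        if len(X) == 0:
            raise ValueError("no complete (wind, concentration) pairs")
        self.X_ = X
        self.y_ = y
        self.obs_weights_ = self._observation_weights(X)

        vmax = self.max_speed if self.max_speed is not None else float(X[:, 1].max())
        vmax = max(vmax, self.speed_step)
        n_sp = int(np.ceil(vmax / self.speed_step))
        speed_edges = np.arange(n_sp + 1) * self.speed_step
        dir_edges = np.linspace(0.0, 360.0, self.n_direction_bins + 1)
        dc = (dir_edges[:-1] + dir_edges[1:]) / 2.0
        sc = (speed_edges[:-1] + speed_edges[1:]) / 2.0
        TH, V = np.meshgrid(dc, sc, indexing="ij")
        w = self._kernel_matrix(TH.ravel(), V.ravel())
        tot = w.sum(axis=1)
        vals = np.full(tot.shape, np.nan)
        ok = tot >= self.weight_floor
        vals[ok] = (w[ok] @ self.y_) / tot[ok]
        self.grid_ = PolarGrid(
            direction_edges=dir_edges,
            speed_edges=speed_edges,
            values=vals.reshape(TH.shape),
            kind="concentration",
        )
        return self

    def predict(self, X):
        """Evaluate the smoothed estimate at arbitrary (direction, speed) points."""
        X = np.asarray(X, dtype=float)
        w = self._kernel_matrix(X[:, 0], X[:, 1])
        tot = w.sum(axis=1)
        out = np.full(len(X), np.nan)
        ok = tot >= self.weight_floor
        out[ok] = (w[ok] @ self.y_) / tot[ok]
        return out


class SustainedWindIncidence(NonparametricWindRegression):
    """SWIM: NWR with sustained (low direction-variability) winds up-weighted.

    Each observation's kernel weight is multiplied by sigma_mean / sigma_i,
    the ratio of the mean Yamartino direction standard deviation to the
    observation's own, so steady winds — which carry the clearest
    source-direction signal — dominate the smoothed surface.  A zero sigma
    is replaced by the smallest positive sigma observed to avoid an
    infinite weight.  ``normalise=True`` additionally scales the fitted
    grid by its maximum to [0, 1].
    """

    def __init__(
        self,
        direction_bandwidth: float = 15.0,
        speed_bandwidth: float = 2.0,
        n_direction_bins: int = 72,
        speed_step: float = 0.5,
        max_speed: float | None = None,
        weight_floor: float = 1e-3,
        normalise: bool = False,
    ):
        super().__init__(
            direction_bandwidth=direction_bandwidth,
            speed_bandwidth=speed_bandwidth,
            n_direction_bins=n_direction_bins,
            speed_step=speed_step,
            max_speed=max_speed,
            weight_floor=weight_floor,
        )
        self.normalise = normalise

    def _observation_weights(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] < 3:
            raise ValueError("SWIM needs a third column: sigma_dir (degrees)")
        sigma = X[:, 2].astype(float).copy()
        if np.isnan(sigma).any():
            raise ValueError("sigma_dir contains missing values")
        if (sigma < 0).any():
            raise ValueError("sigma_dir must be non-negative")
        zero = sigma == 0
        if zero.any():
            positive = sigma[~zero]
            if positive.size == 0:
                raise ValueError("all sigma_dir are zero; SWIM weights undefined")
            sigma[zero] = positive.min()
            logger.warning(
                "replaced %d zero sigma_dir values by the smallest positive (%.3g)",
                int(zero.sum()), positive.min(),
            )
        return sigma.mean() / sigma

    def fit(self, X, y):
        super().fit(X, y)
        if self.normalise:
            peak = np.nanmax(self.grid_.values)
            if peak > 0:
                self.grid_.values = self.grid_.values / peak
            else:
                logger.warning("all concentrations zero; max-normalisation skipped")
        return self


# -- functional wrappers ----------------------------------------------------

def _paired_arrays(conc: pd.Series, wind, need_sigma: bool):
    wf = _as_wind_frame(wind)
    conc = conc.dropna()
    idx = conc.index.intersection(wf.index)
    if len(idx) == 0:
        raise ValueError("no overlapping dates between concentration and wind")
    cols = ["direction", "speed"] + (["sigma_dir"] if need_sigma else [])
    X = wf.loc[idx, cols].to_numpy(dtype=float)
    return X, conc.loc[idx].to_numpy(dtype=float)


def nwr_estimate(conc: pd.Series, wind, **kwargs) -> PolarGrid:
    """Non-parametric wind regression of a concentration series on wind.

    ``conc`` is date-indexed; ``wind`` a DataFrame (columns direction,
    speed[, sigma_dir]) or list of WindObservation sharing dates with it.
    Keyword arguments are forwarded to NonparametricWindRegression.
    """
    X, y = _paired_arrays(conc, wind, need_sigma=False)
    return NonparametricWindRegression(**kwargs).fit(X, y).grid_


def swim_estimate(conc: pd.Series, wind, **kwargs) -> PolarGrid:
    """SWIM polar surface of a concentration series on wind with sigma_dir."""
    X, y = _paired_arrays(conc, wind, need_sigma=True)
    return SustainedWindIncidence(**kwargs).fit(X, y).grid_


def joint_probability_rose(
    wind,
    n_direction_bins: int = 16,
    speed_edges=None,
) -> PolarGrid:
    """Polar histogram of wind occurrence: cell = fraction of observations.

    Direction bins are centred on the compass points (the first bin wraps
    around North).  Default speed edges follow the printed ring scale
    (2/4/8/12 km/h) with a final open band up to the observed maximum.
    """
    wf = _as_wind_frame(wind)
    dirs = wf["direction"].to_numpy(dtype=float)
    speeds = wf["speed"].to_numpy(dtype=float)
    if speed_edges is None:
        top = max(float(speeds.max()) + 1e-9, DEFAULT_SPEED_RINGS[-1] + 1.0)
        speed_edges = np.array(list(DEFAULT_SPEED_RINGS) + [top])
    speed_edges = np.asarray(speed_edges, float)
    width = 360.0 / n_direction_bins
    # rotate by half a bin so bins centre on N, NNE, ...
    shifted = (dirs + width / 2.0) % 360.0
    dir_edges = np.linspace(0.0, 360.0, n_direction_bins + 1)
    counts, _, _ = np.histogram2d(
        shifted, np.clip(speeds, speed_edges[0], speed_edges[-1] - 1e-12),
        bins=[dir_edges, speed_edges],
    )
    probs = counts / counts.sum()
    return PolarGrid(
        direction_edges=dir_edges - width / 2.0,
        speed_edges=speed_edges,
        values=probs,
        kind="probability",
    )


def compass_sector(direction: float, n_sectors: int = 8) -> str:
    """Compass sector label for a direction, sectors centred on compass points."""
    labels = {8: SECTOR_LABELS_8, 16: SECTOR_LABELS_16}[n_sectors]
    idx = int(np.round((direction % 360.0) / (360.0 / n_sectors))) % n_sectors
    return labels[idx]


def dominant_sector(grid: PolarGrid, n_sectors: int = 8):
    """Compass sector and speed band containing the grid maximum.

    Ties are broken towards the lowest speed band, then the first sector
    clockwise from North.  Raises on an all-undefined grid.
    """
    vals = grid.values
    if np.all(np.isnan(vals)):
        raise ValueError("grid has no defined cells")
    peak = np.nanmax(vals)
    cand = np.argwhere(vals == peak)
    dc = grid.direction_centers
    order = sorted(
        (int(i), int(j)) for i, j in cand
    )
    # lowest speed band first, then sector clockwise from N
    width = 360.0 / n_sectors
    order.sort(key=lambda ij: (ij[1], int(np.round(dc[ij[0]] / width)) % n_sectors,
                               dc[ij[0]]))
    i, j = order[0]
    label = compass_sector(dc[i], n_sectors)
    band = (float(grid.speed_edges[j]), float(grid.speed_edges[j + 1]))
    return label, band


def read_wind_table(
    path, dayfirst: bool = True, speed_unit: str = "kmh", sep: str = ","
) -> pd.DataFrame:
    """Read a wind table (date, speed, direction[, sigma_dir]) as a DataFrame.

    ``speed_unit="knots"`` converts speeds to km/h (1 kt = 1.852 km/h),
    matching the archive convention for wind speed.
    """
    df = pd.read_csv(path, sep=sep)
    date_col = df.columns[0]
    idx = pd.DatetimeIndex(
        pd.to_datetime(df[date_col], dayfirst=dayfirst, format="mixed")
    ).normalize()
    out = df.drop(columns=[date_col])
    out.index = idx
    cols = {c.lower(): c for c in out.columns}
    rename = {}
    for want in ("speed", "direction", "sigma_dir"):
        if want in cols:
            rename[cols[want]] = want
    out = out.rename(columns=rename)
    if not {"speed", "direction"} <= set(out.columns):
        raise ValueError(f"{path}: wind table needs 'speed' and 'direction' columns")
    if speed_unit == "knots":
        out["speed"] = out["speed"] * KNOT_TO_KMH
    elif speed_unit != "kmh":
        raise ValueError(f"speed_unit must be 'kmh' or 'knots', got {speed_unit!r}")
    return out


def plot_rose(grid: PolarGrid, path, title: str = "") -> None:
    """Render a PolarGrid as a filled polar plot (meteorological orientation)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    th = np.deg2rad(grid.direction_edges)
    r = grid.speed_edges
    TH, R = np.meshgrid(th, r, indexing="ij")
    vals = np.ma.masked_invalid(grid.values)
    pcm = ax.pcolormesh(TH, R, vals, cmap="viridis", shading="flat")
    fig.colorbar(pcm, ax=ax, label=grid.kind)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
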