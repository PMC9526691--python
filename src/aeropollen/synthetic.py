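"""Synthetic pollen, meteorology and wind data with known ground truth.

Every downstream stage of the package has a generator here that emulates
the statistical structure it assumes, with the planted truth returned
alongside so recovery can be tested:

* unimodal taxon seasons — a gamma-shaped mean curve (rapid rise, slow
  decay, as real pollen curves) scaled to a target Annual Pollen Integral,
  with negative-binomial daily noise (aerobiological counts are
  overdispersed, so Poisson noise would be too kind);
* a bimodal year — a bundle of tree taxa peaking in spring plus grass/herb
  taxa peaking larger in summer, the canonical NW-European season shape;
* wind records with a planted directional plume — concentration elevated
  only when the wind comes from a source sector within a speed band;
* meteorology rank-blended with a pollen series to a target Spearman rho;
* hourly series allocating each day's total across hours around a diurnal
  template with multinomial noise.

All generators are deterministic given (spec, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import HourlySeries, MeteoSeries, TaxonSeries
from .source_receptor import SIGMA_MAX_DEG, angular_distance, compass_sector


@dataclass(frozen=True)
class TaxonSeasonSpec:
    """Ground-truth description of one taxon's synthetic season.

    Days are day-of-year (1-based).  ``apin`` is the noise-free annual sum
    target (pollen·day/m^3).  ``dispersion`` is the negative-binomial size
    parameter (variance = mu + mu^2/dispersion); None disables noise
    entirely (the deterministic mean curve is returned).
    """

    taxon: str
    start_doy: int
    peak_doy: int
    season_length: int
    apin: float
    dispersion: float | None = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.start_doy < self.peak_doy < self.start_doy + self.season_length:
            raise ValueError(
                f"{self.taxon}: need start < peak < start + length, got "
                f"({self.start_doy}, {self.peak_doy}, {self.season_length})"
            )
        if not self.apin > 0:
            raise ValueError(f"{self.taxon}: apin must be > 0")
        if self.dispersion is not None and not self.dispersion > 0:
            raise ValueError(f"{self.taxon}: dispersion must be > 0 or None")


@dataclass(frozen=True)
class PlumeSpec:
    """Planted directional pollen source for wind-regression recovery tests.

    Concentration is ``elevated`` (in expectation) when the wind comes from
    within ``spread`` degrees of ``source_direction`` at a speed inside
    ``speed_band`` (km/h), and ``base`` otherwise.
    """

    source_direction: float = 90.0
    spread: float = 10.0
    speed_band: tuple[float, float] = (8.0, 12.0)
    base: float = 2.0
    elevated: float = 50.0
    dispersion: float | None = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.spread > 0:
            raise ValueError("spread must be > 0")
        if not self.elevated > self.base >= 0:
            raise ValueError("need elevated > base >= 0")
        if not self.speed_band[0] < self.speed_band[1]:
            raise ValueError("speed_band must be (low, high) with low < high")


def season_mean_curve(spec: TaxonSeasonSpec, year: int) -> pd.Series:
    """Noise-free daily mean curve for a season spec, summing to ``apin``.

    The curve is a gamma kernel anchored at ``start_doy`` with its mode at
    ``peak_doy``; the decay scale is set from the post-peak share of
    ``season_length`` so ~the whole season fits inside the stated length.
    """
    full = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doy = np.arange(1, len(full) + 1)
    mode = spec.peak_doy - spec.start_doy
    tail = max((spec.season_length - mode) / 4.0, 0.75)
    shape = 1.0 + mode / tail
    t = doy - spec.start_doy + 0.5  # day-centre offset from season start
    weights = np.where(t > 0, stats.gamma.pdf(np.clip(t, 0, None), shape, scale=tail), 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate season curve")
    return pd.Series(weights / total * spec.apin, index=full, name=spec.taxon)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and size (dispersion) k."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros_like(mu)
    pos = mu > 0
    p = dispersion / (dispersion + mu[pos])
    out[pos] = rng.negative_binomial(dispersion, p)
    return out


def generate_taxon_year(
    spec: TaxonSeasonSpec,
    year: int,
    site: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> TaxonSeries:
    """Draw one taxon-year of daily concentrations around the mean curve.

    With ``dispersion=None`` the noise-free curve itself is returned, so
    the realised APIn equals the target exactly.
    """
    mean = season_mean_curve(spec, year)
    if spec.dispersion is None:
        values = mean
    else:
        rng = rng if rng is not None else np.random.default_rng(spec.seed)
        values = pd.Series(
            _nb_draw(rng, mean.to_numpy(), spec.dispersion),
            index=mean.index, name=spec.taxon,
        )
    return TaxonSeries(site=site, taxon=spec.taxon, values=values)


def true_season_bounds(spec: TaxonSeasonSpec, year: int,
                       lower: float = 0.05, upper: float = 0.95):
    """Noise-free MPS (start, end) dates implied by a season spec."""
    mean = season_mean_curve(spec, year)
    cum = mean.cumsum()
    total = float(mean.sum())
    start = cum.index[np.argmax(cum.to_numpy() >= lower * total)]
    end = cum.index[np.argmax(cum.to_numpy() >= upper * total)]
    return start, end


#: Default season bundle emulating an NW-European (Irish) pollen year:
#: trees pollinate January–May, grasses and herbs June–August with much
#: larger integrals, so the summed total series is bimodal with the summer
#: mode dominant.  APIn magnitudes follow the order observed in urban
#: Ireland (grass/nettle in the 10^4 range, birch/cypress 10^3, rest 10^2-10^3).
DEFAULT_TREE_SPECS = (
    TaxonSeasonSpec("Corylus", start_doy=15, peak_doy=46, season_length=80, apin=160.0),
    TaxonSeasonSpec("Alnus", start_doy=27, peak_doy=46, season_length=45, apin=1500.0),
    TaxonSeasonSpec("Cupressaceae/Taxaceae", start_doy=45, peak_doy=85, season_length=135, apin=5100.0),
    TaxonSeasonSpec("Betula", start_doy=87, peak_doy=108, season_length=50, apin=4900.0),
    TaxonSeasonSpec("Fraxinus", start_doy=78, peak_doy=108, season_length=60, apin=1500.0),
    TaxonSeasonSpec("Quercus", start_doy=112, peak_doy=140, season_length=75, apin=2700.0),
    TaxonSeasonSpec("Pinus", start_doy=125, peak_doy=142, season_length=55, apin=1600.0),
)
DEFAULT_HERB_SPECS = (
    TaxonSeasonSpec("Poaceae", start_doy=158, peak_doy=172, season_length=56, apin=17000.0),
    TaxonSeasonSpec("Urticaceae", start_doy=161, peak_doy=210, season_length=92, apin=15000.0),
    TaxonSeasonSpec("Plantago", start_doy=135, peak_doy=172, season_length=105, apin=370.0),
    TaxonSeasonSpec("Rumex", start_doy=142, peak_doy=172, season_length=62, apin=350.0),
)


def generate_bimodal_year(
    tree_specs=DEFAULT_TREE_SPECS,
    herb_specs=DEFAULT_HERB_SPECS,
    year: int = 2018,
    seed: int = 0,
    site: str = "synthetic",
) -> list[TaxonSeries]:
    """Generate one bimodal pollen year (spring arboreal + summer grass/herb).

    Per-taxon seeds are derived from ``seed`` so the bundle is reproducible
    as a whole.
    """
    specs = list(tree_specs) + list(herb_specs)
    if not specs:
        raise ValueError("need at least one taxon spec")
    rng = np.random.default_rng(seed)
    return [generate_taxon_year(s, year, site=site, rng=rng) for s in specs]


def generate_wind_with_plume(
    spec: PlumeSpec,
    n_days: int,
    year: int = 2018,
    seed: int | None = None,
):
    """Wind records plus a concentration series with a planted source.

    Directions are uniform on the circle; speeds are gamma-distributed
    (shape 2, scale 4 km/h, mean 8 km/h).  Concentration is drawn around
    ``elevated`` on days the wind comes from the source (direction within
    ``spread`` of ``source_direction`` and speed inside ``speed_band``) and
    around ``base`` otherwise.  The per-day Yamartino sigma is drawn low
    (5–15°) on source days — a sustained plume — and broad (15–60°)
    otherwise.  Returns (wind DataFrame, concentration Series, truth dict
    with the planted compass sector).
    """
    if n_days <= 0:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    dates = pd.date_range(f"{year}-01-01", periods=n_days, freq="D")
    directions = rng.uniform(0.0, 360.0, n_days)
    speeds = rng.gamma(shape=2.0, scale=4.0, size=n_days)
    in_plume = (
        (angular_distance(directions, spec.source_direction) <= spec.spread)
        & (speeds >= spec.speed_band[0])
        & (speeds <= spec.speed_band[1])
    )
    mu = np.where(in_plume, spec.elevated, spec.base)
    if spec.dispersion is None:
        conc = mu.astype(float)
    else:
        conc = _nb_draw(rng, mu, spec.dispersion)
    sigma = np.where(
        in_plume, rng.uniform(5.0, 15.0, n_days), rng.uniform(15.0, 60.0, n_days)
    )
    wind = pd.DataFrame(
        {"speed": speeds, "direction": directions,
         "sigma_dir": np.clip(sigma, 0.0, SIGMA_MAX_DEG)},
        index=dates,
    )
    truth = {
        "sector": compass_sector(spec.source_direction),
        "source_direction": spec.source_direction,
        "speed_band": list(spec.speed_band),
        "n_plume_days": int(in_plume.sum()),
    }
    return wind, pd.Series(conc, index=dates, name="concentration"), truth


def generate_meteo_with_association(
    pollen: TaxonSeries | pd.Series,
    param: str = "Tmean",
    rho_target: float = 0.6,
    seed: int = 0,
    site: str = "synthetic",
):
    """Meteorological series rank-blended with a pollen series.

    The parameter is built on a Gaussian copula: the pollen ranks are
    mapped to normal scores and mixed with independent noise at the Pearson
    coefficient 2·sin(pi·rho_target/6), the value whose induced Spearman
    correlation equals ``rho_target``.  Returns (MeteoSeries, realised
    Spearman rho) so tests can use the realised value as ground truth.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must lie in [-1, 1]")
    values = pollen.values if isinstance(pollen, TaxonSeries) else pollen
    obs = values.dropna()
    n = len(obs)
    if n < 3:
        raise ValueError("need at least 3 observed pollen days")
    rng = np.random.default_rng(seed)
    ranks = obs.rank(method="average").to_numpy()
    z = stats.norm.ppf((ranks - 0.5) / n)
    if abs(rho_target) == 1.0:
        blended = z * math.copysign(1.0, rho_target)
    else:
        rho_p = 2.0 * math.sin(math.pi * rho_target / 6.0)
        blended = rho_p * z + math.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
    met_vals = 10.0 + 5.0 * blended  # plausible temperature-like scale
    realised = float(stats.spearmanr(obs.to_numpy(), met_vals)[0])
    data = pd.DataFrame({param: met_vals}, index=obs.index)
    return MeteoSeries(site=site, data=data), realised


def generate_hourly(
    daily: TaxonSeries,
    template,
    seed: int = 0,
    site: str | None = None,
) -> HourlySeries:
    """Allocate each day's total across hours around a 24-weight template.

    For each observed day, N ≈ 24 × (daily concentration) grain-equivalents
    are distributed over the 24 hours multinomially with probabilities
    proportional to the template, then rescaled so the day's mean equals
    the daily value exactly.  Days with zero (or missing) concentration get
    zero (or missing) hours.
    """
    template = np.asarray(template, dtype=float)
    if template.shape != (24,) or (template < 0).any() or template.sum() <= 0:
        raise ValueError("template must be 24 non-negative weights with positive sum")
    probs = template / template.sum()
    rng = np.random.default_rng(seed)
    stamps: list[pd.Timestamp] = []
    values: list[float] = []
    for date, conc in daily.values.items():
        hours = pd.date_range(date, periods=24, freq="h")
        if np.isnan(conc):
            continue
        total = conc * 24.0
        n_grains = int(round(total))
        if n_grains == 0:
            hourly = np.zeros(24)
        else:
            counts = rng.multinomial(n_grains, probs)
            hourly = counts * (total / n_grains)
        stamps.extend(hours)
        values.extend(hourly)
    return HourlySeries(
        site=site or daily.site,
        taxon=daily.taxon,
        values=pd.Series(values, index=pd.DatetimeIndex(stamps)),
    )
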