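"""Pollen–meteorology association screening.

Daily pollen concentrations are rarely normal (nor log-normal), so the
screening pipeline is deliberately non-parametric: a Lilliefors test
documents the departure from normality, and Spearman rank correlations
quantify monotone association between concentrations and meteorological
parameters.  Correlations are computed either over the days of a taxon's
Main Pollen Season (season-scale screening) or per calendar month
(phenology-scale screening).

No multiple-testing correction is applied by default — each (taxon,
parameter) pair is reported marginally — but Benjamini–Hochberg adjustment
can be switched on.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors
from statsmodels.stats.multitest import multipletests

from .io import MeteoSeries, TaxonSeries
from .seasons import SeasonStats

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Spearman correlation of one taxon with one parameter in one scope."""

    taxon: str
    parameter: str
    scope: str
    rho: float
    p_value: float
    n: int
    significant: bool

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rho)


def _ks_normal_stat(values: np.ndarray) -> float:
    """KS distance between the ECDF and a normal fitted by mean/SD."""
    x = np.sort(values)
    n = len(x)
    cdf = stats.norm.cdf(x, loc=x.mean(), scale=x.std(ddof=1))
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def lilliefors_test(
    values,
    method: str = "approx",
    n_reps: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Lilliefors test of composite normality: (statistic, p value).

    The statistic is the Kolmogorov–Smirnov distance between the empirical
    CDF and a normal CDF with mean and SD estimated from the sample — the
    estimation is what distinguishes Lilliefors from plain KS and what the
    null distribution must account for.  ``method="approx"`` uses the
    standard table-based approximation; ``method="mc"`` draws the null
    distribution by seeded Monte-Carlo simulation (``n_reps`` standard
    normal samples of the same size).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 4:
        raise ValueError(f"Lilliefors test needs n >= 4, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: standard deviation is degenerate")
    if method == "approx":
        stat, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
        return float(stat), float(p)
    if method != "mc":
        raise ValueError(f"method must be 'approx' or 'mc', got {method!r}")
    stat = _ks_normal_stat(x)
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for i in range(n_reps):
        null[i] = _ks_normal_stat(rng.standard_normal(len(x)))
    p = (1.0 + np.sum(null >= stat)) / (n_reps + 1.0)
    return float(stat), float(p)


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation on complete pairs: (rho, p, n).

    Ties receive average ranks; the p value uses the t approximation with
    n − 2 degrees of freedom.  Fewer than 3 complete pairs, or zero rank
    variance in either variable, yields (nan, nan, n) rather than an error
    so matrix construction can flag rather than drop the pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n


def _correlate_window(
    taxon: str,
    pollen: pd.Series,
    met_data: pd.DataFrame,
    scope: str,
    alpha: float,
    params,
) -> list[CorrelationResult]:
    results = []
    for param in params:
        joined = pd.concat([pollen, met_data[param]], axis=1, join="inner")
        rho, p, n = spearman(joined.iloc[:, 0], joined.iloc[:, 1])
        results.append(
            CorrelationResult(
                taxon=taxon, parameter=param, scope=scope, rho=rho,
                p_value=p, n=n,
                significant=bool(np.isfinite(p) and p < alpha),
            )
        )
    return results


def mps_correlation_matrix(
    pollen: list[TaxonSeries],
    met: MeteoSeries,
    seasons: list[SeasonStats],
    alpha: float = 0.05,
    params: list[str] | None = None,
    adjust: str | None = None,
) -> list[CorrelationResult]:
    """Spearman correlations restricted to each taxon's Main Pollen Season.

    One result per (taxon, parameter) pair using only dates within the
    taxon's [start, end]; taxa without a defined season are skipped with a
    warning.  Derived parameters already present in ``met`` (e.g. 10-day
    trailing means) participate like any other column.
    ``adjust="bh"`` re-flags significance after Benjamini–Hochberg.
    """
    params = params or list(met.data.columns)
    by_taxon = {s.taxon: s for s in pollen}
    results: list[CorrelationResult] = []
    for season in seasons:
        series = by_taxon.get(season.taxon)
        if series is None:
            logger.warning("no pollen series for season row %s; skipped", season.taxon)
            continue
        if not season.defined:
            logger.warning(
                "%s %d has no defined MPS; skipped", season.taxon, season.year
            )
            continue
        window = series.values.loc[season.start_date: season.end_date].dropna()
        results.extend(
            _correlate_window(
                season.taxon, window, met.data,
                scope=f"MPS-{season.year}", alpha=alpha, params=params,
            )
        )
    if adjust == "bh":
        _apply_bh(results, alpha)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


def monthly_correlation(
    pollen: TaxonSeries,
    met: MeteoSeries,
    alpha: float = 0.05,
    params: list[str] | None = None,
    min_days: int = 10,
    adjust: str | None = None,
) -> list[CorrelationResult]:
    """Per-calendar-month Spearman correlations of one (usually Total) series.

    Months with fewer than ``min_days`` complete pollen days are skipped
    with a warning; scope labels are "YYYY-MM".
    """
    params = params or list(met.data.columns)
    results: list[CorrelationResult] = []
    values = pollen.values.dropna()
    for (year, month), chunk in values.groupby([values.index.year, values.index.month]):
        if len(chunk) < min_days:
            logger.warning(
                "%s %04d-%02d: only %d paired days (<%d); skipped",
                pollen.taxon, year, month, len(chunk), min_days,
            )
            continue
        results.extend(
            _correlate_window(
                pollen.taxon, chunk, met.data,
                scope=f"{year:04d}-{month:02d}", alpha=alpha, params=params,
            )
        )
    if adjust == "bh":
        _apply_bh(results, alpha)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


def _apply_bh(results: list[CorrelationResult], alpha: float) -> None:
    defined = [r for r in results if np.isfinite(r.p_value)]
    if not defined:
        return
    reject, *_ = multipletests([r.p_value for r in defined], alpha=alpha, method="fdr_bh")
    for r, rej in zip(defined, reject):
        r.significant = bool(rej)


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Long-format DataFrame of correlation results."""
    return pd.DataFrame(
        {
            "taxon": [r.taxon for r in results],
            "parameter": [r.parameter for r in results],
            "scope": [r.scope for r in results],
            "rho": [r.rho for r in results],
            "p_value": [r.p_value for r in results],
            "n": [r.n for r in results],
            "significant": [r.significant for r in results],
        }
    )


def correlation_matrix_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Wide matrix (taxon/scope rows × parameter columns) with '*' markers."""
    def cell(r: CorrelationResult) -> str:
        if not r.defined:
            return ""
        return f"{r.rho:.2f}{'*' if r.significant else ''}"

    df = pd.DataFrame(
        {
            "row": [f"{r.taxon} [{r.scope}]" for r in results],
            "parameter": [r.parameter for r in results],
            "cell": [cell(r) for r in results],
        }
    )
    return df.pivot(index="row", columns="parameter", values="cell")
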