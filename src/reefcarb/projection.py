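"""Decadal forward simulation of available sediment volume under declining
aragonite saturation, with linear trend fitting and erosive-year
extrapolation.

For each simulated year, the inorganic rate G_i is obtained per season and
zone by trapezoidal tidal-cycle averaging of the rate law over a generated
hydrochemical series; the four seasonal values are averaged with equal
weights; the per-pixel production map and the platform budget are then
computed with the benthic community (A_c) and rugosity held fixed across
years.  A straight line is fitted to the volume series and extrapolated to
its zero crossing (the onset of an erosive state); both the full-series and
the endpoint extrapolations are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .budget import DEFAULT_BULK_DENSITY, available_sediment, export_flux, integrate_production
from .production import CalcifierTable, RateLawParams, compute_gnet, inorganic_rate
from .raster import Raster
from .synthetic import SEASONS, HydrochemSeries, OmegaTrajectory, generate_hydrochem

__all__ = [
    "TrendFit",
    "ProjectionSeries",
    "tidal_average_rate",
    "seasonal_zone_rates",
    "project",
    "fit_trend",
    "erosive_year",
]


@dataclass(frozen=True)
class TrendFit:
    """OLS straight-line fit of available volume on calendar year."""

    slope: float  # m^3 yr^-1 per yr
    intercept: float  # m^3 yr^-1 at year 0 (calendar scale)
    r_squared: float
    slope_stderr: float


@dataclass
class ProjectionSeries:
    """Decadal projected volumes, the G_i values used, and the fitted trend."""

    years: np.ndarray
    available_volume: np.ndarray  # m^3 yr^-1
    gross_production: np.ndarray  # kg yr^-1
    export_mass: float
    bulk_density: float
    gi_table: pd.DataFrame  # columns: year, season, zone, gi
    trend: TrendFit | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.years) != len(self.available_volume):
            raise ValueError("one volume per year required")
        if self.trend is None and len(self.years) >= 3:
            self.trend = fit_trend(self.years, self.available_volume)

    @property
    def erosive_year_trend(self) -> float | None:
        """Zero crossing of the fitted line (None if not declining)."""
        return erosive_year(self.trend) if self.trend is not None else None

    @property
    def erosive_year_endpoints(self) -> float | None:
        """Zero crossing of the line through the first and last points."""
        dv = self.available_volume[-1] - self.available_volume[0]
        dy = self.years[-1] - self.years[0]
        if dy == 0 or dv >= 0:
            return None
        slope = dv / dy
        return float(self.years[0] - self.available_volume[0] / slope)

    def to_frame(self) -> pd.DataFrame:
        gi = self.gi_table.pivot_table(
            index="year", columns=["zone", "season"], values="gi"
        )
        gi.columns = [f"gi_{z}_{s}" for z, s in gi.columns]
        df = pd.DataFrame(
            {"year": self.years, "gross_kg_yr": self.gross_production,
             "export_kg_yr": self.export_mass,
             "available_volume_m3_yr": self.available_volume}
        ).set_index("year")
        return df.join(gi).reset_index()


def tidal_average_rate(series: HydrochemSeries, params: RateLawParams | None = None) -> float:
    """Time-weighted (trapezoidal) mean of the inorganic rate over a cycle."""
    if len(series.times) == 0:
        raise ValueError("empty hydrochemical series")
    rates = inorganic_rate(series.omega, series.temperature, params)
    if len(series.times) == 1:
        warnings.warn("single-sample series; returning the point rate")
        return float(np.asarray(rates).ravel()[0])
    return float(np.trapezoid(rates, series.times) / (series.times[-1] - series.times[0]))


def seasonal_zone_rates(
    trajectory: OmegaTrajectory,
    year: float,
    params: RateLawParams | None = None,
    seed: int = 0,
    **hydrochem_kwargs,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Equal-weight seasonal average of tidal-cycle G_i for both zones.

    Returns ({"flat": gi, "slope": gi}, table of the per-season values).
    The hydrochemical series for each (season, zone) is generated with a
    deterministic child seed derived from ``seed`` and the combination.
    """
    rows = []
    gi_by_zone: dict[str, float] = {}
    for zi, zone in enumerate(("flat", "slope")):
        seasonal = []
        for si, season in enumerate(SEASONS):
            child = (seed * 1_000_003 + int(round(year)) * 101 + si * 11 + zi) % (2**31)
            series = generate_hydrochem(
                zone, season, year, trajectory, seed=child, **hydrochem_kwargs
            )
            gi = tidal_average_rate(series, params)
            seasonal.append(gi)
            rows.append({"year": year, "season": season, "zone": zone, "gi": gi})
        gi_by_zone[zone] = float(np.mean(seasonal))
    return gi_by_zone, pd.DataFrame(rows)


def project(
    covers: Mapping[str, Raster],
    rugosity: Raster,
    zone_mask: Raster,
    trajectory: OmegaTrajectory,
    table: CalcifierTable | None = None,
    params: RateLawParams | None = None,
    *,
    perimeter: float,
    unit_flux: float,
    bulk_density: float = DEFAULT_BULK_DENSITY,
    years: np.ndarray | None = None,
    seed: int = 0,
    **hydrochem_kwargs,
) -> ProjectionSeries:
    """Run the decadal forward simulation with the community held fixed.

    ``covers`` and ``rugosity`` are not adjusted across years; only the
    chemistry (G_i per season and zone) changes with the trajectory.
    """
    if years is None:
        years = trajectory.years
    years = np.asarray(years, dtype=float)
    missing = [y for y in years
               if not (trajectory.years[0] <= y <= trajectory.years[-1])]
    if missing:
        raise ValueError(f"trajectory does not cover year(s): {missing}")
    export = export_flux(perimeter, unit_flux)
    volumes, grosses, gi_frames = [], [], []
    for year in years:
        gi_by_zone, gi_frame = seasonal_zone_rates(
            trajectory, year, params, seed=seed, **hydrochem_kwargs
        )
        gi_frames.append(gi_frame)
        gnet = compute_gnet(covers, rugosity, zone_mask, gi_by_zone, table)
        gross = integrate_production(gnet)
        result = available_sediment(gross, export, bulk_density)
        grosses.append(gross)
        volumes.append(result.available_volume)
    return ProjectionSeries(
        years=years,
        available_volume=np.asarray(volumes),
        gross_production=np.asarray(grosses),
        export_mass=export,
        bulk_density=bulk_density,
        gi_table=pd.concat(gi_frames, ignore_index=True),
    )


def fit_trend(years: np.ndarray, volumes: np.ndarray) -> TrendFit:
    """Ordinary least squares of available volume on calendar year."""
    years = np.asarray(years, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if len(years) < 2:
        raise ValueError("need at least 2 years to fit a trend")
    if np.ptp(years) == 0:
        raise ValueError("degenerate input: all years identical")
    res = stats.linregress(years, volumes)
    return TrendFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), slope_stderr=float(res.stderr),
    )


def erosive_year(trend: TrendFit) -> float | None:
    """Calendar year at which the fitted line reaches zero volume.

    Returns None ("beyond horizon") when the trend is not declining.
    """
    if trend.slope >= 0:
        return None
    return float(-trend.intercept / trend.slope)
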