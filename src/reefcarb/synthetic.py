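"""Seeded synthetic reef scenes, hydrochemistry, island DEMs and transects.

Every downstream stage of the package is exercised on data from this module:
a reef platform with flat/slope zonation and known generative cover model, a
declining aragonite-saturation trajectory reaching the end-century values
mean 2.13 (diurnal limits 3.95 / 0.85), tidal-cycle hydrochemical series with
reef-flat ponding amplification, island DEMs with closed-form volume, and
ReefBudget-style census transects drawn from the scene's own covers.

All generators take explicit integer seeds; identical seeds and parameters
yield bit-identical outputs.  Ground truth (the generative beta coefficients)
is recorded on the scene so that the habitat regression's recovery can be
checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from . import terrain
from .census import TransectRecord
from .habitat import COVARIATES, CoverSample
from .production import PRODUCERS
from .raster import GridSpec, Raster, read_ascii, write_ascii
from .terrain import BathymetryParams

__all__ = [
    "SceneParams",
    "ReefScene",
    "OmegaTrajectory",
    "HydrochemSeries",
    "IslandParams",
    "generate_scene",
    "generate_omega_trajectory",
    "generate_hydrochem",
    "generate_island_dem",
    "generate_transects",
    "sample_cover_points",
]

SEASONS = ("summer", "autumn", "winter", "spring")

#: seasonal water temperature, deg C (southern GBR reef flat)
SEASON_TEMPERATURES = {"summer": 27.0, "autumn": 24.5, "winter": 21.5, "spring": 24.0}

#: generative betas: [intercept, b1, b2, depth, slope, rugosity]
_DEFAULT_COVER_BETAS = {
    "branching_coral": [0.00, 0.0, 0.0, 0.027, 0.004, 0.06],
    "nonbranching_coral": [0.38, 0.0, 0.15, -0.024, 0.0, 0.0],
    "cca": [0.37, -0.02, 0.0, -0.022, -0.003, 0.0],
    "halimeda": [0.03, 0.0, 0.0, 0.025, 0.0, 0.0],
}


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters of a synthetic reef platform.

    The depth field is a radially zoned platform (shallow flat, ramp to a
    deep apron) with smoothed random relief; reflectance band 1 is built by
    inverting the log band-ratio bathymetry model at the true depths so that
    the optical and bathymetric layers are mutually consistent; covers follow
    a linear model of (b1, b2, depth, slope, rugosity) plus clipped Gaussian
    noise.  See docs/methods.md for the rationale of each default.
    """

    flat_depth: float = 0.8  # m, typical reef-flat depth
    max_depth: float = 15.0  # m, lower forereef
    flat_fraction: float = 0.5  # target areal fraction of the reef flat
    ramp_width: float = 210.0  # m, crest-to-lower-forereef slope width
    zone_depth_threshold: float = 3.0  # m, flat/slope mask split
    relief_amplitude: float = 2.5  # m, depth-scaled random relief
    relief_smoothing: float = 1.0  # cells, Gaussian smoothing of relief
    bathymetry: BathymetryParams = field(default_factory=BathymetryParams)
    b2_range: tuple[float, float] = (0.1, 0.5)
    reflectance_noise_sd: float = 0.04  # multiplicative, both bands
    cover_betas: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_COVER_BETAS.items()}
    )
    cover_noise_sd: float = 0.02  # fine-scale community patchiness
    perimeter_length: float = 4395.0  # m, reef-crest perimeter


@dataclass
class ReefScene:
    """Co-registered rasters describing one reef platform, with ground truth."""

    grid: GridSpec
    dem: Raster  # depth, m below datum (positive down)
    reflectance_b1: Raster
    reflectance_b2: Raster
    zone_mask: Raster  # 1 = reef flat, 0 = reef slope
    slope: Raster  # degrees, derived from dem
    rugosity: Raster  # k'_r, derived from dem
    true_cover: dict[str, Raster]
    params: SceneParams
    perimeter_length: float
    platform_area: float  # m^2

    def covariate_rasters(self) -> dict[str, Raster]:
        return {
            "reflectance_b1": self.reflectance_b1,
            "reflectance_b2": self.reflectance_b2,
            "depth": self.dem,
            "slope": self.slope,
            "rugosity": self.rugosity,
        }

    def valid_mask(self) -> np.ndarray:
        """Cells where every covariate and cover layer is defined."""
        mask = np.isfinite(self.dem.values)
        for r in (self.slope, self.rugosity, self.reflectance_b1,
                  self.reflectance_b2, *self.true_cover.values()):
            mask &= np.isfinite(r.values)
        return mask

    def write(self, outdir: str | Path) -> None:
        """Write every layer as an ASCII grid plus a JSON metadata sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        layers = {"dem": self.dem, "reflectance_b1": self.reflectance_b1,
                  "reflectance_b2": self.reflectance_b2, "zone_mask": self.zone_mask,
                  "slope": self.slope, "rugosity": self.rugosity}
        layers.update({f"cover_{p}": r for p, r in self.true_cover.items()})
        for name, raster in layers.items():
            write_ascii(raster, outdir / f"{name}.asc")
        meta = {
            "perimeter_length_m": self.perimeter_length,
            "platform_area_m2": self.platform_area,
            "cover_betas": {k: list(map(float, v))
                            for k, v in self.params.cover_betas.items()},
            "covariate_order": list(COVARIATES),
        }
        (outdir / "scene.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def generate_scene(
    spec: GridSpec, params: SceneParams | None = None, seed: int = 0
) -> ReefScene:
    """Generate a seeded synthetic reef platform scene.

    The cover fields are drawn from the linear generative model recorded in
    ``params.cover_betas`` (clipped to [0, 1]; cells whose covers would sum
    above 1 are rescaled proportionally), so the habitat regression can be
    checked against known truth.
    """
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    x, y = spec.cell_centers()
    width, height = spec.extent
    cx = spec.origin[0] + width / 2.0
    cy = spec.origin[1] - height / 2.0
    r = np.hypot(x - cx, y - cy)

    # radius at which depth reaches the zone threshold, chosen so the flat
    # mask covers ~flat_fraction of the grid; the ramp starts further in
    total_area = width * height
    ramp_width = min(params.ramp_width, 0.45 * min(width, height))
    r_threshold = np.sqrt(params.flat_fraction * total_area / np.pi)
    ramp_gradient = (params.max_depth - params.flat_depth) / ramp_width
    r_flat = r_threshold - (params.zone_depth_threshold - params.flat_depth) / ramp_gradient

    depth = params.flat_depth + np.clip(r - r_flat, 0.0, ramp_width) * ramp_gradient
    relief = gaussian_filter(rng.standard_normal(spec.shape), params.relief_smoothing)
    sd = relief.std()
    if sd > 0:
        relief /= sd
    depth_scale = 0.3 + 0.7 * depth / params.max_depth  # more relief on the slope
    depth = np.clip(depth + params.relief_amplitude * depth_scale * relief,
                    0.2, params.max_depth)  # apron flattens at the lower forereef
    dem = Raster(depth, spec)

    # reflectance: b2 is an independent smooth field; b1 inverts the
    # band-ratio depth model at the true depths, then both get noise
    lo, hi = params.b2_range
    b2 = gaussian_filter(rng.standard_normal(spec.shape), 2.0)
    span = b2.max() - b2.min()
    b2 = lo + (hi - lo) * (b2 - b2.min()) / (span if span > 0 else 1.0)
    bp = params.bathymetry
    b1 = np.exp(np.log(bp.n_scale * b2) * (depth + bp.m0) / bp.m1) / bp.n_scale
    if params.reflectance_noise_sd > 0:
        b1 = b1 * np.exp(params.reflectance_noise_sd * rng.standard_normal(spec.shape))
        b2 = b2 * np.exp(params.reflectance_noise_sd * rng.standard_normal(spec.shape))
    b1r, b2r = Raster(b1, spec), Raster(b2, spec)

    slope = terrain.derive_slope(dem)
    rugosity = terrain.derive_rugosity(dem)
    zone_mask = Raster((depth <= params.zone_depth_threshold).astype(float), spec)

    covariates = np.stack(
        [b1, b2, depth, slope.values, rugosity.values]
    )
    covers: dict[str, Raster] = {}
    raw = {}
    for producer in PRODUCERS:
        beta = np.asarray(params.cover_betas[producer], dtype=float)
        eta = beta[0] + np.tensordot(beta[1:], covariates, axes=1)
        if params.cover_noise_sd > 0:
            eta = eta + params.cover_noise_sd * rng.standard_normal(spec.shape)
        raw[producer] = np.clip(eta, 0.0, 1.0)
    total = sum(raw.values())
    with np.errstate(invalid="ignore"):
        scale = np.where(total > 1.0, total, 1.0)
    for producer in PRODUCERS:
        covers[producer] = Raster(raw[producer] / scale, spec)

    return ReefScene(
        grid=spec, dem=dem, reflectance_b1=b1r, reflectance_b2=b2r,
        zone_mask=zone_mask, slope=slope, rugosity=rugosity, true_cover=covers,
        params=params, perimeter_length=params.perimeter_length,
        platform_area=total_area,
    )


# ---------------------------------------------------------------------------
# aragonite saturation trajectory and tidal-cycle hydrochemistry


@dataclass
class OmegaTrajectory:
    """Decadal reef-flat aragonite saturation trajectory with diurnal limits.

    ``seasonal_means[season]`` holds one mean per stored year.  The reef
    slope follows the flat with its decline attenuated by
    ``slope_decline_fraction`` (ponding amplifies acidification over the
    flat, so offshore slope water declines less).
    """

    years: np.ndarray
    seasonal_means: dict[str, np.ndarray]
    diurnal_upper: np.ndarray
    diurnal_lower: np.ndarray
    slope_decline_fraction: float = 0.6

    def __post_init__(self) -> None:
        means = np.mean([self.seasonal_means[s] for s in SEASONS], axis=0)
        if np.any(self.diurnal_lower > means) or np.any(means > self.diurnal_upper):
            raise ValueError("diurnal limits must bracket the annual mean")
        if np.any(np.diff(means) > 1e-12):
            raise ValueError("annual means must be non-increasing")

    def _interp(self, series: np.ndarray, year: float) -> float:
        if not (self.years[0] <= year <= self.years[-1]):
            raise ValueError(
                f"year {year} outside trajectory range "
                f"{self.years[0]}-{self.years[-1]}"
            )
        return float(np.interp(year, self.years, series))

    def _attenuate(self, value: float, series: np.ndarray, zone: str) -> float:
        if zone == "flat":
            return value
        if zone == "slope":
            start = float(series[0])
            return start + self.slope_decline_fraction * (value - start)
        raise ValueError(f"unknown zone '{zone}' (expected 'flat' or 'slope')")

    def annual_mean(self, year: float, zone: str = "flat") -> float:
        means = np.mean([self.seasonal_means[s] for s in SEASONS], axis=0)
        return self._attenuate(self._interp(means, year), means, zone)

    def seasonal_mean(self, year: float, season: str, zone: str = "flat") -> float:
        if season not in SEASONS:
            raise ValueError(f"unknown season '{season}' (expected one of {SEASONS})")
        series = self.seasonal_means[season]
        return self._attenuate(self._interp(series, year), series, zone)

    def diurnal_limits(self, year: float, zone: str = "flat") -> tuple[float, float]:
        lower = self._attenuate(self._interp(self.diurnal_lower, year),
                                self.diurnal_lower, zone)
        upper = self._attenuate(self._interp(self.diurnal_upper, year),
                                self.diurnal_upper, zone)
        return lower, upper


def generate_omega_trajectory(
    start_year: int = 2000,
    end_year: int = 2100,
    start_mean: float = 3.2,
    end_mean: float = 2.13,
    shape: str = "exponential",
    step: int = 10,
    start_upper: float = 4.1,
    start_lower: float = 2.4,
    end_upper: float = 3.95,
    end_lower: float = 0.85,
    seasonal_offsets: Mapping[str, float] | None = None,
    acceleration: float = 1.3,
    slope_decline_fraction: float = 0.6,
) -> OmegaTrajectory:
    """Decadal Omega trajectory interpolating the given endpoints.

    ``shape='exponential'`` gives an accelerating decline (year-on-year
    decrements strictly increasing in magnitude, tracking the growth of
    atmospheric CO2 under a high-emissions scenario); ``'linear'`` gives
    constant decrements.  Defaults reach the end-century reef-flat values
    mean 2.13 with diurnal limits 3.95 and 0.85.
    """
    if start_year >= end_year:
        raise ValueError("start_year must be < end_year")
    if start_mean <= 0 or end_mean <= 0:
        raise ValueError("Omega endpoints must be positive")
    if shape not in ("exponential", "linear"):
        raise ValueError(f"unknown shape '{shape}'")
    years = np.arange(start_year, end_year + 1, step)
    if years[-1] != end_year:
        years = np.append(years, end_year)
    u = (years - start_year) / (end_year - start_year)
    if shape == "exponential":
        progress = (np.exp(acceleration * u) - 1.0) / (np.exp(acceleration) - 1.0)
    else:
        progress = u
    offsets = dict(seasonal_offsets or {"summer": 0.15, "autumn": 0.0,
                                        "winter": -0.15, "spring": 0.0})
    means = start_mean + (end_mean - start_mean) * progress
    return OmegaTrajectory(
        years=years.astype(float),
        seasonal_means={s: means + offsets.get(s, 0.0) for s in SEASONS},
        diurnal_upper=start_upper + (end_upper - start_upper) * progress,
        diurnal_lower=start_lower + (end_lower - start_lower) * progress,
        slope_decline_fraction=slope_decline_fraction,
    )


@dataclass
class HydrochemSeries:
    """Omega and temperature over one tidal-cycle window for a zone/season."""

    times: np.ndarray  # hours within the window, strictly increasing
    omega: np.ndarray
    temperature: np.ndarray  # deg C
    zone: str
    season: str
    year: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.omega <= 0):
            raise ValueError("Omega must be strictly positive")


def _trapezoid_mean(values: np.ndarray, times: np.ndarray) -> float:
    return float(np.trapezoid(values, times) / (times[-1] - times[0]))


def generate_hydrochem(
    zone: str,
    season: str,
    year: float,
    trajectory: OmegaTrajectory,
    ponding_amplitude: float = 1.2,
    seed: int = 0,
    window_hours: float = 7.0,
    time_step: float = 0.5,
    noise_sd: float = 0.02,
    slope_amplitude_fraction: float = 0.3,
) -> HydrochemSeries:
    """Tidal-cycle Omega/temperature series for one zone, season and year.

    The series oscillates around the trajectory's seasonal mean with
    half-amplitude ``ponding_amplitude`` on the reef flat (where water ponds
    at low tide and metabolic processes drive large excursions) and
    ``slope_amplitude_fraction`` of that on the slope.  Excursions are capped
    by the trajectory's diurnal limits for the year, and the series is
    recentred so its time-weighted (trapezoidal) mean equals the seasonal
    mean exactly.
    """
    if zone not in ("flat", "slope"):
        raise ValueError(f"unknown zone '{zone}' (expected 'flat' or 'slope')")
    if season not in SEASONS:
        raise ValueError(f"unknown season '{season}' (expected one of {SEASONS})")
    if ponding_amplitude < 0:
        raise ValueError("ponding_amplitude must be >= 0")
    mean = trajectory.seasonal_mean(year, season, zone)
    lower, upper = trajectory.diurnal_limits(year, zone)
    amp = ponding_amplitude if zone == "flat" else slope_amplitude_fraction * ponding_amplitude
    amp_up = min(amp, max(upper - mean, 0.0))
    amp_down = min(amp, max(mean - lower, 0.0))

    times = np.arange(0.0, window_hours + 0.5 * time_step, time_step)
    w = np.cos(2.0 * np.pi * times / window_hours)  # one full tidal oscillation
    omega = mean + amp_up * np.maximum(w, 0.0) - amp_down * np.maximum(-w, 0.0)
    if noise_sd > 0:
        omega = omega + noise_sd * np.random.default_rng(seed).standard_normal(len(times))
    omega = omega + (mean - _trapezoid_mean(omega, times))  # exact mean
    omega = np.maximum(omega, 1e-6)

    temperature = SEASON_TEMPERATURES[season] + 0.3 * w
    return HydrochemSeries(times, omega, temperature, zone, season, float(year))


# ---------------------------------------------------------------------------
# island DEM


@dataclass(frozen=True)
class IslandParams:
    """Closed-form island surface: paraboloid dome with north-south ridges.

    The surface is z = h * (1 - (r/R)^2)_+ * (1 + eps * sin(pi * n * dx / R))
    with dx the east-west offset from the island centre.  The ridge term is
    odd in dx, so the continuum volume is exactly the dome volume
    pi * R^2 * h / 2 regardless of the ridges.  Defaults reproduce the scale
    of a 0.43 km^2 shingle cay with volume ~1.84e6 m^3.
    """

    radius: float = 370.0  # m
    height: float = 8.55  # m, crest height above base level
    ridge_amplitude_fraction: float = 0.15  # eps, must be < 1
    n_ridges: int = 6
    noise_sd: float = 0.0  # m, optional seeded roughness (zero-mean)

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.height > 0):
            raise ValueError("radius and height must be > 0")
        if not 0 <= self.ridge_amplitude_fraction < 1:
            raise ValueError("ridge_amplitude_fraction must be in [0, 1)")

    @property
    def analytic_volume(self) -> float:
        """Exact continuum volume above base level, m^3."""
        return 0.5 * np.pi * self.radius**2 * self.height


def generate_island_dem(
    spec: GridSpec, ridge_params: IslandParams | None = None, seed: int = 0
) -> tuple[Raster, float]:
    """Island elevation DEM (m above base level) and its analytic volume."""
    params = ridge_params or IslandParams()
    x, y = spec.cell_centers()
    width, height_ext = spec.extent
    cx = spec.origin[0] + width / 2.0
    cy = spec.origin[1] - height_ext / 2.0
    r2 = ((x - cx) ** 2 + (y - cy) ** 2) / params.radius**2
    dome = params.height * np.maximum(1.0 - r2, 0.0)
    ridges = 1.0 + params.ridge_amplitude_fraction * np.sin(
        np.pi * params.n_ridges * (x - cx) / params.radius
    )
    z = dome * ridges
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = params.noise_sd * rng.standard_normal(spec.shape)
        z = np.maximum(z + np.where(dome > 0, noise - noise.mean(), 0.0), 0.0)
    return Raster(z, spec), params.analytic_volume


# ---------------------------------------------------------------------------
# census transects and ground samples


def generate_transects(
    scene: ReefScene,
    n_sites: int = 5,
    length: float = 10.0,
    seed: int = 0,
    transects_per_site: int = 2,
    depth_band: tuple[float, float] = (3.5, 10.5),
    cover_noise_sd: float = 0.05,
    max_segment_length: float = 1.0,
) -> list[TransectRecord]:
    """ReefBudget-style transect records drawn from the scene's true covers.

    Sites are placed on reef-slope cells, stratified across the given depth
    band (transects in the field are deployed around different aspects of
    the slope).  For each transect the conforming length is
    d1 = length * rugosity at the cell, segment lengths follow the cell's
    covers perturbed by multiplicative noise (tape-census measurement
    error), and the non-calcifying remainder is recorded as sand.
    """
    if length <= 0:
        raise ValueError("transect length must be > 0")
    rng = np.random.default_rng(seed)
    mask = scene.valid_mask() & (scene.zone_mask.values == 0)
    depth = scene.dem.values
    mask &= (depth >= depth_band[0]) & (depth <= depth_band[1])
    rows, cols = np.nonzero(mask)
    if len(rows) < n_sites * transects_per_site:
        raise ValueError("not enough valid reef-slope cells for the requested sites")
    # stratify cells by depth so sites span the band
    order = np.argsort(depth[rows, cols])
    n_transects = n_sites * transects_per_site
    strata = np.array_split(order, n_transects)
    records: list[TransectRecord] = []
    for idx, stratum in enumerate(strata):
        pick = stratum[rng.integers(len(stratum))]
        i, j = rows[pick], cols[pick]
        site = f"site{idx // transects_per_site + 1}-t{idx % transects_per_site + 1}"
        rug = scene.rugosity.values[i, j] * (1.0 + 0.02 * abs(rng.standard_normal()))
        d1 = length * rug
        covers = {p: scene.true_cover[p].values[i, j] for p in PRODUCERS}
        noisy = {p: c * np.exp(cover_noise_sd * rng.standard_normal())
                 for p, c in covers.items()}
        total_cover = sum(noisy.values())
        if total_cover > 1.0:
            noisy = {p: c / total_cover for p, c in noisy.items()}
            total_cover = 1.0
        lengths = {p: c * d1 for p, c in noisy.items()}
        lengths["sand"] = (1.0 - total_cover) * d1
        # subdivide each taxon's length into pieces and shuffle for realism
        pieces: list[tuple[str, float]] = []
        for taxon, total in lengths.items():
            if total <= 1e-9:
                continue
            n_pieces = max(1, int(np.ceil(total / max_segment_length)))
            for _ in range(n_pieces):
                pieces.append((taxon, total / n_pieces))
        rng.shuffle(pieces)
        x = scene.grid.origin[0] + (j + 0.5) * scene.grid.cell_size
        y = scene.grid.origin[1] - (i + 0.5) * scene.grid.cell_size
        records.append(TransectRecord(site, pieces, d1=d1, d2=length, location=(x, y)))
    return records


def sample_cover_points(
    scene: ReefScene,
    n: int,
    seed: int = 0,
    cover_noise_sd: float = 0.0,
) -> list[CoverSample]:
    """Ground-reference samples of covers + covariates at random valid cells.

    Observation noise (additive Gaussian, clipped to [0, 1]) emulates field
    estimation error of percent cover; covariates are read exactly.
    """
    rng = np.random.default_rng(seed)
    mask = scene.valid_mask()
    rows, cols = np.nonzero(mask)
    if len(rows) < n:
        raise ValueError(f"only {len(rows)} valid cells for {n} samples")
    picks = rng.choice(len(rows), size=n, replace=False)
    covariate_rasters = scene.covariate_rasters()
    samples = []
    for p in picks:
        i, j = rows[p], cols[p]
        x = scene.grid.origin[0] + (j + 0.5) * scene.grid.cell_size
        y = scene.grid.origin[1] - (i + 0.5) * scene.grid.cell_size
        covers = {}
        for producer in PRODUCERS:
            value = scene.true_cover[producer].values[i, j]
            if cover_noise_sd > 0:
                value = value + cover_noise_sd * rng.standard_normal()
            covers[producer] = float(np.clip(value, 0.0, 1.0))
        covariates = {c: float(covariate_rasters[c].values[i, j]) for c in COVARIATES}
        samples.append(CoverSample(x, y, covers, covariates))
    return samples


def read_scene(indir: str | Path) -> ReefScene:
    """Read a scene previously written with :meth:`ReefScene.write`."""
    indir = Path(indir)
    meta = json.loads((indir / "scene.json").read_text())
    layers = {name: read_ascii(indir / f"{name}.asc")
              for name in ("dem", "reflectance_b1", "reflectance_b2",
                           "zone_mask", "slope", "rugosity")}
    covers = {p: read_ascii(indir / f"cover_{p}.asc") for p in PRODUCERS}
    params = replace(SceneParams(), cover_betas=meta["cover_betas"])
    return ReefScene(
        grid=layers["dem"].grid, dem=layers["dem"],
        reflectance_b1=layers["reflectance_b1"],
        reflectance_b2=layers["reflectance_b2"],
        zone_mask=layers["zone_mask"], slope=layers["slope"],
        rugosity=layers["rugosity"], true_cover=covers, params=params,
        perimeter_length=meta["perimeter_length_m"],
        platform_area=meta["platform_area_m2"],
    )
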