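"""Rate-law core: inorganic aragonite precipitation, community calcification
fraction, and per-pixel net community calcification.

The chemistry-driven reference rate is a power law in the aragonite
saturation state anomaly,

    G_i = k(T) * sign(Omega - 1) * |Omega - 1| ** n(T),

zero at Omega = 1 and negative in the dissolution regime Omega < 1.  The
coefficient ``k`` and exponent ``n`` (and their optional linear temperature
sensitivities about a reference temperature) are explicit, reconstructed
defaults; see docs/methods.md.  The community calcification fraction A_c of a
pixel is the cover-weighted mean calcification rate of its producers
normalised by the fastest producer:

    A_c = sum_i P_i * K_c_i / K_max,   in [0, 1],

and net community calcification is the product G_net = A_c * k'_r * G_i with
k'_r the terrain rugosity and G_i chosen per pixel from the reef-flat or
reef-slope chemistry via the zone mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .raster import Raster, require_coregistered

__all__ = [
    "PRODUCERS",
    "CalcifierTable",
    "RateLawParams",
    "inorganic_rate",
    "compute_Ac",
    "compute_gnet",
]

#: canonical producer keys, in a fixed order used throughout the package
PRODUCERS = ("branching_coral", "nonbranching_coral", "cca", "halimeda")

#: Pacific calcification rates, kg CaCO3 m^-2 yr^-1
_PACIFIC_RATES = {
    "branching_coral": 10.0,
    "nonbranching_coral": 3.0,
    "cca": 1.49,
    "halimeda": 1.80,
}


@dataclass(frozen=True)
class CalcifierTable:
    """Per-producer calcification rates K_c and the normalising maximum K_max."""

    rates: Mapping[str, float] = field(default_factory=lambda: dict(_PACIFIC_RATES))

    def __post_init__(self) -> None:
        if not self.rates:
            raise ValueError("calcifier table must contain at least one producer")
        for name, rate in self.rates.items():
            if not rate > 0:
                raise ValueError(f"calcification rate for '{name}' must be > 0")

    @property
    def k_max(self) -> float:
        return max(self.rates.values())

    def rate(self, producer: str) -> float:
        try:
            return self.rates[producer]
        except KeyError:
            raise KeyError(
                f"unknown producer '{producer}'; known: {sorted(self.rates)}"
            ) from None


@dataclass(frozen=True)
class RateLawParams:
    """Power-law parameters for inorganic aragonite precipitation.

    ``k`` (kg CaCO3 m^-2 yr^-1) and ``n_exp`` are reconstructed defaults; the
    optional linear temperature sensitivities act about ``t_ref`` (deg C).
    ``clamp_dissolution`` clips negative rates (Omega < 1) to zero.
    """

    k: float = 0.7
    n_exp: float = 1.7
    t_ref: float = 25.0
    k_temp_slope: float = 0.0  # relative change of k per deg C
    n_temp_slope: float = 0.0  # additive change of n per deg C
    clamp_dissolution: bool = False

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"rate coefficient k must be > 0, got {self.k}")
        if not self.n_exp > 0:
            raise ValueError(f"exponent n_exp must be > 0, got {self.n_exp}")

    def with_k(self, k: float) -> "RateLawParams":
        return RateLawParams(
            k, self.n_exp, self.t_ref, self.k_temp_slope, self.n_temp_slope,
            self.clamp_dissolution,
        )


def inorganic_rate(
    omega: float | np.ndarray,
    temperature: float | np.ndarray = 25.0,
    params: RateLawParams | None = None,
):
    """Inorganic aragonite precipitation rate G_i, kg CaCO3 m^-2 yr^-1.

    Signed power law in (Omega - 1): zero at saturation, negative in the
    dissolution regime unless ``params.clamp_dissolution``.
    """
    params = params or RateLawParams()
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("aragonite saturation state must be > 0")
    dt = np.asarray(temperature, dtype=float) - params.t_ref
    k = params.k * (1.0 + params.k_temp_slope * dt)
    n = params.n_exp + params.n_temp_slope * dt
    x = omega - 1.0
    gi = k * np.sign(x) * np.abs(x) ** n
    if params.clamp_dissolution:
        gi = np.maximum(gi, 0.0)
    return float(gi) if gi.ndim == 0 else gi


def compute_Ac(
    covers: Mapping[str, float | np.ndarray],
    table: CalcifierTable | None = None,
):
    """Community calcification fraction A_c from proportional covers.

    ``covers`` maps producer name to cover fraction (scalar or array).  Covers
    must lie in [0, 1] and sum to <= 1; unknown producer keys are rejected.
    """
    table = table or CalcifierTable()
    total = None
    cover_sum = None
    for name, frac in covers.items():
        rate = table.rate(name)  # raises on unknown producer
        frac = np.asarray(frac, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((frac < -1e-12) | (frac > 1 + 1e-12)):
                raise ValueError(f"cover for '{name}' outside [0, 1]")
        term = frac * rate
        total = term if total is None else total + term
        cover_sum = frac if cover_sum is None else cover_sum + frac
    if total is None:
        raise ValueError("covers mapping is empty")
    with np.errstate(invalid="ignore"):
        if np.any(cover_sum > 1 + 1e-9):
            raise ValueError("covers sum to more than 1")
    ac = total / table.k_max
    return float(ac) if ac.ndim == 0 else ac


def compute_gnet(
    covers: Mapping[str, Raster],
    rugosity: Raster,
    zone_mask: Raster,
    gi_by_zone: Mapping[str, float],
    table: CalcifierTable | None = None,
) -> Raster:
    """Per-pixel net community calcification G_net = A_c * k'_r * G_i(zone).

    Parameters
    ----------
    covers:
        Cover raster per producer, co-registered.
    rugosity:
        Terrain rugosity raster k'_r (>= 1 where valid).
    zone_mask:
        Binary raster: 1 = reef flat, 0 = reef slope.
    gi_by_zone:
        ``{"flat": G_i, "slope": G_i}`` in kg CaCO3 m^-2 yr^-1; a conditional
        statement inserts the correct value per pixel.

    Nodata in any input propagates to the output.
    """
    table = table or CalcifierTable()
    missing = {"flat", "slope"} - set(gi_by_zone)
    if missing:
        raise ValueError(f"missing G_i for zone(s): {sorted(missing)}")
    grid = require_coregistered(rugosity=rugosity, zone_mask=zone_mask, **covers)
    ac = compute_Ac({k: r.values for k, r in covers.items()}, table)
    gi = np.where(zone_mask.values == 1, gi_by_zone["flat"], gi_by_zone["slope"])
    gi = np.where(np.isfinite(zone_mask.values), gi, np.nan)
    return Raster(ac * rugosity.values * gi, grid)
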