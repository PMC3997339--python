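"""Platform carbonate budget: integration, export, sediment volume, and the
historic island-accretion reconstruction.

The available sediment volume is a first-order mass balance: gross carbonate
production integrated over the platform, minus the mass exported past the
reef perimeter, converted to volume with a bulk density for loose biogenic
carbonate sediment.  Negative volumes (erosive budgets) are reported, not
clamped.  Historic accretion divides island volume above base level by the
time since deposition began.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raster import Raster

__all__ = [
    "DEFAULT_BULK_DENSITY",
    "BudgetResult",
    "IslandGeometry",
    "integrate_production",
    "export_flux",
    "available_sediment",
    "island_volume",
    "historic_accretion",
    "percent_reduction",
]

#: kg m^-3, loose biogenic carbonate sand/rubble (reconstructed default;
#: exposed in every config and report)
DEFAULT_BULK_DENSITY = 1300.0


@dataclass(frozen=True)
class BudgetResult:
    """Annual platform carbonate budget.  Masses kg yr^-1, volume m^3 yr^-1.

    Closure: available_volume * bulk_density == gross_production - export_mass.
    """

    gross_production: float
    export_mass: float
    bulk_density: float
    available_volume: float

    def __post_init__(self) -> None:
        if not self.bulk_density > 0:
            raise ValueError("bulk_density must be > 0")


@dataclass(frozen=True)
class IslandGeometry:
    """Island volume, age since deposition began, and mean accretion rate."""

    volume: float  # m^3
    age: float  # years
    accretion_rate: float  # m^3 yr^-1


def integrate_production(gnet: Raster, cell_area: float | None = None) -> float:
    """Total platform production, kg CaCO3 yr^-1 (nodata cells contribute 0)."""
    if cell_area is None:
        cell_area = gnet.grid.cell_area
    if not cell_area > 0:
        raise ValueError("cell_area must be > 0")
    valid = gnet.valid_mask
    if not valid.any():
        raise ValueError("cannot integrate an all-nodata raster")
    return float(np.sum(gnet.values[valid]) * cell_area)


def export_flux(perimeter: float, unit_flux: float) -> float:
    """Annual export mass past the reef perimeter, kg yr^-1."""
    if perimeter < 0 or unit_flux < 0:
        raise ValueError("perimeter and unit flux must be non-negative")
    return perimeter * unit_flux


def available_sediment(
    gross: float, export: float, bulk_density: float = DEFAULT_BULK_DENSITY
) -> BudgetResult:
    """Available sediment volume per year from the mass balance.

    May be negative (erosive budget); the closure identity
    volume * density = gross - export holds exactly.
    """
    if not bulk_density > 0:
        raise ValueError("bulk_density must be > 0")
    volume = (gross - export) / bulk_density
    return BudgetResult(gross, export, bulk_density, volume)


def island_volume(
    dem: Raster, base_level: float = 0.0, cell_area: float | None = None
) -> float:
    """Island volume above base level, m^3: sum of max(z - base, 0) * area."""
    if cell_area is None:
        cell_area = dem.grid.cell_area
    if not cell_area > 0:
        raise ValueError("cell_area must be > 0")
    above = np.maximum(dem.values - base_level, 0.0)
    above = np.where(np.isfinite(above), above, 0.0)
    if not (above > 0).any():
        warnings.warn("no DEM cell lies above base level; volume is 0")
        return 0.0
    return float(above.sum() * cell_area)


def historic_accretion(volume: float, age: float) -> IslandGeometry:
    """Mean historic accretion rate: island volume divided by island age."""
    if not age > 0:
        raise ValueError("island age must be > 0")
    return IslandGeometry(volume=volume, age=age, accretion_rate=volume / age)


def percent_reduction(initial: float, final: float) -> float:
    """Percent reduction of ``final`` relative to ``initial``."""
    if initial == 0:
        raise ValueError("initial value must be nonzero")
    return 100.0 * (initial - final) / initial
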