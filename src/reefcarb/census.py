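"""Transect census estimator of net carbonate production (ReefBudget-style,
Pacific rates) and the comparison of census against rate-law estimates.

A transect record lists contiguous (taxon, surface length) segments measured
with a tape conforming to the substrate (total conforming length d1) together
with the planar length d2; site rugosity is d1/d2.  Census production per
planar square metre is the surface-length-weighted sum of calcification
rates, so rugosity enters through d1 > d2:

    G = sum_calcifier (length_i * K_c_i) / d2     [kg CaCO3 m^-2 yr^-1]

Non-calcifying covers (sand, rubble, turf, dead coral, soft coral,
macroalgae) contribute zero; no bioerosion debit is applied.  Coral growth
forms map onto the two coral rate classes (branching -> 10, encrusting/
massive/platy -> 3 kg CaCO3 m^-2 yr^-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .production import CalcifierTable

__all__ = [
    "NON_CALCIFIERS",
    "GROWTH_FORM_TO_PRODUCER",
    "TransectRecord",
    "transect_rugosity",
    "census_gnet",
    "compare_census_to_ratelaw",
    "read_transects_csv",
    "write_transects_csv",
]

#: covers recorded by the census that deposit no carbonate
NON_CALCIFIERS = frozenset(
    {"sand", "rubble", "turf_algae", "macroalgae", "soft_coral", "dead_coral"}
)

#: growth-form / taxon labels -> canonical producer keys
GROWTH_FORM_TO_PRODUCER = {
    "branching_coral": "branching_coral",
    "encrusting_coral": "nonbranching_coral",
    "massive_coral": "nonbranching_coral",
    "platy_coral": "nonbranching_coral",
    "nonbranching_coral": "nonbranching_coral",
    "cca": "cca",
    "halimeda": "halimeda",
}


@dataclass
class TransectRecord:
    """One census transect: ordered segments plus tape lengths d1 >= d2."""

    site: str
    segments: Sequence[tuple[str, float]]
    d1: float  # conforming (surface) tape length, m
    d2: float  # planar length, m
    location: tuple[float, float] | None = None  # (x, y) of the site, m

    def __post_init__(self) -> None:
        if not self.d2 > 0:
            raise ValueError(f"{self.site}: planar length d2 must be > 0")
        if self.d1 < self.d2 - 1e-9:
            raise ValueError(f"{self.site}: conforming length d1 must be >= d2")
        if any(length <= 0 for _, length in self.segments):
            raise ValueError(f"{self.site}: segment lengths must be > 0")
        total = sum(length for _, length in self.segments)
        if abs(total - self.d1) > 1e-6 * max(self.d1, 1.0):
            raise ValueError(
                f"{self.site}: segment lengths sum to {total}, expected d1={self.d1}"
            )


def transect_rugosity(record: TransectRecord) -> float:
    """Site rugosity d1/d2 (>= 1)."""
    return record.d1 / record.d2


def census_gnet(
    record: TransectRecord,
    table: CalcifierTable | None = None,
    non_calcifiers: frozenset[str] = NON_CALCIFIERS,
) -> float:
    """Census net carbonate production per planar m^2, kg CaCO3 m^-2 yr^-1."""
    table = table or CalcifierTable()
    total = 0.0
    for taxon, length in record.segments:
        if taxon in non_calcifiers:
            continue
        producer = GROWTH_FORM_TO_PRODUCER.get(taxon, taxon)
        if producer not in table.rates:
            raise ValueError(
                f"{record.site}: unknown taxon '{taxon}' (not a calcifier in the "
                f"table and not in the non-calcifier list)"
            )
        total += length * table.rate(producer)
    return total / record.d2


def compare_census_to_ratelaw(
    census: Mapping[str, float], ratelaw: Mapping[str, float]
) -> tuple[float, pd.DataFrame]:
    """R^2 between paired census and rate-law production values.

    Sites must match exactly between the two mappings; returns the coefficient
    of determination (squared Pearson correlation of the pairs) and the
    pairing table.
    """
    if set(census) != set(ratelaw):
        only_c = sorted(set(census) - set(ratelaw))
        only_r = sorted(set(ratelaw) - set(census))
        raise ValueError(
            f"site labels differ: census-only {only_c}, rate-law-only {only_r}"
        )
    if len(census) < 3:
        raise ValueError("need at least 3 paired sites")
    sites = sorted(census)
    x = np.array([census[s] for s in sites])
    y = np.array([ratelaw[s] for s in sites])
    r = stats.pearsonr(x, y).statistic
    table = pd.DataFrame({"site": sites, "census": x, "rate_law": y})
    return float(r**2), table


def write_transects_csv(records: Iterable[TransectRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        x, y = rec.location if rec.location is not None else (np.nan, np.nan)
        for order, (taxon, length) in enumerate(rec.segments):
            rows.append(
                {"site": rec.site, "segment": order, "taxon": taxon,
                 "length_m": length, "d1_m": rec.d1, "d2_m": rec.d2,
                 "x_m": x, "y_m": y}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_transects_csv(path: str | Path) -> list[TransectRecord]:
    df = pd.read_csv(path)
    records = []
    for site, grp in df.groupby("site", sort=True):
        grp = grp.sort_values("segment")
        segments = list(zip(grp["taxon"], grp["length_m"].astype(float)))
        location = None
        if "x_m" in grp and np.isfinite(grp["x_m"].iloc[0]):
            location = (float(grp["x_m"].iloc[0]), float(grp["y_m"].iloc[0]))
        records.append(
            TransectRecord(
                str(site), segments, float(grp["d1_m"].iloc[0]),
                float(grp["d2_m"].iloc[0]), location=location,
            )
        )
    return records
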