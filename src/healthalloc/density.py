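"""Health resource density index (HRDI) and the standardized index W.

HRDI combines demographic and geographic access in one number: the
geometric mean of the resource count per 1,000 population and the count per
square kilometer.  Because it is a geometric mean, scaling a region's count
by c scales its HRDI by c, and the index stays unit-coherent (sqrt of
[count²/(person·km²)] up to the 1,000 factor).

W standardizes a region's HRDI against a reference level — by default the
province aggregate (total resources over total population and total area
for the same year), so a region shaped exactly like the province gets
W = 1.  W > 1 marks above-average allocation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import RESOURCES, Panel


@dataclass(frozen=True)
class DensityIndexResult:
    region_id: str
    year: int
    resource: str
    per_1000_pop: float
    per_km2: float
    hrdi: float
    w: float | None = None


def hrdi(
    resource_count: float,
    population: float,
    area_km2: float,
    method: str = "geometric_mean",
) -> float:
    """Density index of one region-resource.

    ``method="geometric_mean"`` (default) returns
    sqrt((count/population × 1000) × (count/area)); ``method="product"``
    returns the bare product, available for sensitivity checks only.
    """
    if population <= 0 or area_km2 <= 0:
        raise ValueError("population and area must be positive")
    if resource_count < 0:
        raise ValueError("resource count must be non-negative")
    per_pop = resource_count / population * 1000.0
    per_area = resource_count / area_km2
    if method == "geometric_mean":
        return float(np.sqrt(per_pop * per_area))
    if method == "product":
        return float(per_pop * per_area)
    raise ValueError(f"unknown method {method!r}")


def w_index(
    resource_count: float,
    population: float,
    area_km2: float,
    standard_count: float,
    standard_population: float,
    standard_area_km2: float,
    method: str = "geometric_mean",
) -> float:
    """W = HRDI_region / HRDI_standard for one region-resource-year."""
    h_std = hrdi(standard_count, standard_population, standard_area_km2, method)
    if h_std == 0:
        raise ZeroDivisionError("standard HRDI is zero; W undefined")
    return hrdi(resource_count, population, area_km2, method) / h_std


def density_table(panel: Panel, resources=RESOURCES) -> pd.DataFrame:
    """Long-format per-region densities: per-1,000-population and per-km²
    rates plus HRDI, for every region × resource × year."""
    rows = []
    for year in panel.years:
        sl = panel.year_slice(year)
        for _, rec in sl.iterrows():
            for res in resources:
                rows.append(
                    {
                        "region_id": rec["region_id"],
                        "year": year,
                        "resource": res,
                        "per_1000_pop": rec[res] / rec["population"] * 1000.0,
                        "per_km2": rec[res] / rec["area_km2"],
                        "hrdi": hrdi(rec[res], rec["population"], rec["area_km2"]),
                    }
                )
    return pd.DataFrame(rows)


def w_table(
    panel: Panel,
    resources=RESOURCES,
    standard: str = "aggregate",
    method: str = "geometric_mean",
) -> pd.DataFrame:
    """W for every region × resource × year, long format.

    ``standard="aggregate"`` (default) builds the reference HRDI from
    province totals; ``standard="mean"`` uses the unweighted mean of the
    regional HRDIs instead.
    """
    if standard not in ("aggregate", "mean"):
        raise ValueError("standard must be 'aggregate' or 'mean'")
    rows = []
    for year in panel.years:
        sl = panel.year_slice(year)
        tot = panel.aggregate_totals(year)
        for res in resources:
            if standard == "aggregate":
                h_std = hrdi(
                    getattr(tot, res), tot.population, tot.area_km2, method
                )
            else:
                h_std = float(
                    np.mean(
                        [
                            hrdi(r[res], r["population"], r["area_km2"], method)
                            for _, r in sl.iterrows()
                        ]
                    )
                )
            if h_std == 0:
                raise ZeroDivisionError(
                    f"standard HRDI is zero for {res} in {year}; W undefined"
                )
            for _, rec in sl.iterrows():
                h = hrdi(rec[res], rec["population"], rec["area_km2"], method)
                rows.append(
                    {
                        "region_id": rec["region_id"],
                        "year": year,
                        "resource": res,
                        "hrdi": h,
                        "hrdi_standard": h_std,
                        "w": h / h_std,
                    }
                )
    return pd.DataFrame(rows)


def w_grid(w_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long W table into a region × (resource, year) grid."""
    grid = w_long.pivot_table(
        index="region_id", columns=["resource", "year"], values="w", sort=False
    )
    return grid


def flag_w_extremes(
    w_long: pd.DataFrame, low: float = 1.0, high: float = 1.8
) -> pd.DataFrame:
    """Per-region reporting flags: all W below ``low`` (under-resourced in
    every resource-year) or all W above ``high`` (well above average)."""
    grouped = w_long.groupby("region_id", sort=False)["w"]
    return pd.DataFrame(
        {
            "all_below_1": grouped.apply(lambda s: bool((s < low).all())),
            "all_above_1_8": grouped.apply(lambda s: bool((s > high).all())),
        }
    )
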