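"""Panel data model for regional health-resource series.

A panel holds one row per (region, year) with population, geographic area,
four health-resource counts (beds, health technicians, licensed/assistant
physicians, registered nurses) and two service-utilization counts
(consultations, hospital admissions).  Counts are stored as floats because
yearbook series may report annual averages; validation enforces
non-negativity only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical CSV column order.
SCHEMA: tuple[str, ...] = (
    "region_id",
    "year",
    "population",
    "area_km2",
    "beds",
    "health_technicians",
    "licensed_physicians",
    "registered_nurses",
    "consultations",
    "admissions",
)

#: Resource columns used as equity indicators and DEA inputs.
RESOURCES: tuple[str, ...] = (
    "beds",
    "health_technicians",
    "licensed_physicians",
    "registered_nurses",
)

#: Service-utilization columns used as DEA outputs.
UTILIZATION: tuple[str, ...] = ("consultations", "admissions")

_NUMERIC = SCHEMA[2:]


class PanelSchemaError(ValueError):
    """A required column is missing or mis-typed."""


class PanelValidationError(ValueError):
    """A cell violates the panel invariants (sign, finiteness)."""


class PanelDuplicateError(ValueError):
    """The same (region_id, year) appears more than once."""


@dataclass(frozen=True)
class RegionYearRecord:
    """One region-year observation."""

    region_id: str
    year: int
    population: float
    area_km2: float
    beds: float
    health_technicians: float
    licensed_physicians: float
    registered_nurses: float
    consultations: float
    admissions: float


class Panel:
    """Validated collection of :class:`RegionYearRecord` rows.

    Rows are normalized to (region_id, year) order internally; region
    display order follows first appearance in the input, and no analytic
    result depends on input order.
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate(frame)
        first_seen = frame["region_id"].astype(str).drop_duplicates().tolist()
        self.regions: list[str] = first_seen
        self.years: list[int] = sorted(self._frame["year"].unique().tolist())

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[RegionYearRecord]) -> "Panel":
        return cls(pd.DataFrame([r.__dict__ for r in records], columns=SCHEMA))

    @classmethod
    def read(
        cls,
        path: str | Path,
        format: str | None = None,
        sheet_name: str | int = 0,
        column_mapping: Mapping[str, str] | None = None,
    ) -> "Panel":
        """Read a panel from CSV (canonical schema) or XLSX.

        The XLSX reader is a thin adapter: ``column_mapping`` maps schema
        names to the source headers of the sheet, so supplementary tables
        with arbitrary headers can be ingested without editing the file.
        """
        path = Path(path)
        if format is None:
            format = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
        if format == "csv":
            raw = pd.read_csv(path)
        elif format == "xlsx":
            raw = pd.read_excel(path, sheet_name=sheet_name, engine="openpyxl")
            if column_mapping:
                missing_src = [v for v in column_mapping.values() if v not in raw.columns]
                if missing_src:
                    raise PanelSchemaError(
                        f"mapped source columns not found in sheet: {missing_src}"
                    )
                raw = raw.rename(columns={v: k for k, v in column_mapping.items()})
        else:
            raise ValueError(f"unknown format {format!r}")
        return cls(raw)

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """Copy of the validated rows, sorted by (region_id, year)."""
        return self._frame.copy()

    @property
    def records(self) -> list[RegionYearRecord]:
        return [RegionYearRecord(**row) for row in self._frame.to_dict("records")]

    @property
    def is_complete(self) -> bool:
        """True when every region × year combination occurs exactly once."""
        return len(self._frame) == len(self.regions) * len(self.years)

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        a = self._frame.reset_index(drop=True)
        b = other._frame.reset_index(drop=True)
        return a.equals(b)

    def year_slice(self, year: int) -> pd.DataFrame:
        """Rows for one year, ordered by region display order."""
        if year not in self.years:
            raise LookupError(f"year {year} not present in panel")
        sl = self._frame[self._frame["year"] == year]
        order = {r: i for i, r in enumerate(self.regions)}
        return sl.sort_values("region_id", key=lambda s: s.map(order)).reset_index(
            drop=True
        )

    def region_slice(self, region_id: str) -> pd.DataFrame:
        if region_id not in self.regions:
            raise LookupError(f"region {region_id!r} not present in panel")
        return self._frame[self._frame["region_id"] == region_id].reset_index(drop=True)

    # -- operations --------------------------------------------------------

    def aggregate_totals(self, year: int) -> RegionYearRecord:
        """Sum every numeric field across regions for one year.

        The result (region_id ``"TOTAL"``) is the province-level observation
        used when years act as DEA decision units.
        """
        sl = self.year_slice(year)
        sums = sl[list(_NUMERIC)].sum()
        return RegionYearRecord(region_id="TOTAL", year=int(year), **sums.to_dict())

    def totals_frame(self) -> pd.DataFrame:
        """Province totals for every year, one row per year."""
        rows = [self.aggregate_totals(y).__dict__ for y in self.years]
        return pd.DataFrame(rows, columns=SCHEMA)

    def write(self, path: str | Path) -> None:
        """Write the canonical CSV (UTF-8, full precision)."""
        self._frame.to_csv(path, index=False)


def read_panel(path: str | Path, format: str | None = None, **kwargs) -> Panel:
    """Functional alias for :meth:`Panel.read`."""
    return Panel.read(path, format=format, **kwargs)


def write_panel(panel: Panel, path: str | Path) -> None:
    panel.write(path)


def merge_population_area(resource_table: pd.DataFrame, pop_area_table: pd.DataFrame) -> pd.DataFrame:
    """Join a resource/utilization table with a separate population-area table.

    Yearbook extracts sometimes carry resources and demographics in separate
    files; both must share ``region_id`` and ``year`` keys.
    """
    for col in ("region_id", "year"):
        if col not in resource_table.columns or col not in pop_area_table.columns:
            raise PanelSchemaError(f"both tables must carry {col!r}")
    merged = resource_table.merge(
        pop_area_table[["region_id", "year", "population", "area_km2"]],
        on=["region_id", "year"],
        how="left",
        validate="one_to_one",
    )
    return merged


def _validate(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCHEMA if c not in frame.columns]
    if missing:
        raise PanelSchemaError(f"missing required column(s): {missing}")
    df = frame.loc[:, list(SCHEMA)].copy()
    df["region_id"] = df["region_id"].astype(str)
    try:
        df["year"] = df["year"].astype(int)
    except (TypeError, ValueError) as exc:
        raise PanelSchemaError(f"year column is not integer-valued: {exc}") from exc
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)

    dup = df.duplicated(subset=["region_id", "year"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["region_id", "year"]].drop_duplicates().values.tolist()
        raise PanelDuplicateError(f"duplicate (region, year) pairs: {pairs}")

    for col in _NUMERIC:
        bad = ~np.isfinite(df[col].to_numpy())
        if bad.any():
            where = df.loc[bad, ["region_id", "year"]].iloc[0].tolist()
            raise PanelValidationError(
                f"non-finite value in field {col!r} at (region, year) = {tuple(where)}"
            )
    for col in ("population", "area_km2"):
        bad = df[col].to_numpy() <= 0
        if bad.any():
            where = df.loc[bad, ["region_id", "year"]].iloc[0].tolist()
            raise PanelValidationError(
                f"{col} must be > 0; violated at (region, year) = {tuple(where)}"
            )
    for col in RESOURCES + UTILIZATION:
        bad = df[col].to_numpy() < 0
        if bad.any():
            where = df.loc[bad, ["region_id", "year"]].iloc[0].tolist()
            raise PanelValidationError(
                f"{col} must be >= 0; violated at (region, year) = {tuple(where)}"
            )
    return df.sort_values(["region_id", "year"]).reset_index(drop=True)
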