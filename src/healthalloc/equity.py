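"""Lorenz curves, Gini coefficients and equity classification.

Equity of a resource allocation is measured against an allocation base —
population (demographic access) or geographic area (spatial access).  The
Lorenz curve plots the cumulative share of the base on the x-axis against
the cumulative share of the resource on the y-axis, with regions ordered by
resource per unit of the active base in ascending order; the Gini
coefficient is twice the area between the curve and the 45° equity line,

    G = 2 × [ 0.5 − 1/2 · Σ_i (X_i − X_{i−1})(Y_i + Y_{i−1}) ],

with X_0 = Y_0 = 0 prepended and n the number of regions.  G = 0 is perfect
equity; values of 0.6 and above are conventionally read as a dangerous
degree of inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import RESOURCES, Panel

BASE_COLUMNS = {"population": "population", "geography": "area_km2"}

#: Equity bands, lower-edge inclusive (g = 0.2 falls in "relatively_fair").
EQUITY_BANDS: tuple[tuple[float, str], ...] = (
    (0.2, "absolute_equity"),
    (0.3, "relatively_fair"),
    (0.4, "basically_reasonable"),
    (0.5, "gap_0.4_0.5"),
    (0.6, "wide_gap"),
    (np.inf, "dangerous_inequality"),
)


class DegenerateCurveError(ValueError):
    """All-zero resource total: cumulative shares are undefined."""


@dataclass(frozen=True)
class LorenzCurve:
    """Ordered cumulative-share polyline from (0,0) to (1,1).

    ``points`` has shape (n_regions + 1, 2); column 0 is the cumulative
    base share X, column 1 the cumulative resource share Y.
    """

    points: np.ndarray
    base: str
    resource: str | None = None
    year: int | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("points must be an (k, 2) array with k >= 2")
        x, y = pts[:, 0], pts[:, 1]
        tol = 1e-9
        if abs(x[0]) > tol or abs(y[0]) > tol:
            raise ValueError("curve must start at (0, 0)")
        if abs(x[-1] - 1) > tol or abs(y[-1] - 1) > tol:
            raise ValueError("curve must end at (1, 1)")
        if np.any(np.diff(x) < -tol) or np.any(np.diff(y) < -tol):
            raise ValueError("cumulative shares must be non-decreasing")

    @property
    def n_regions(self) -> int:
        return self.points.shape[0] - 1

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class GiniResult:
    value: float
    band: str
    n_regions: int


def lorenz_curve(
    values,
    bases,
    base_kind: str = "population",
    resource: str | None = None,
    year: int | None = None,
) -> LorenzCurve:
    """Build the Lorenz curve of ``values`` against allocation base ``bases``.

    Regions are sorted ascending by value/base (resource per unit of the
    active base) so the polyline is convex and lies on or below the
    diagonal.  Ties keep input order; the Gini coefficient is unaffected by
    tie order.
    """
    v = np.asarray(values, dtype=float)
    b = np.asarray(bases, dtype=float)
    if v.shape != b.shape or v.ndim != 1:
        raise ValueError("values and bases must be 1-d arrays of equal length")
    if len(v) < 2:
        raise ValueError("at least 2 regions are required")
    if np.any(b <= 0) or not np.all(np.isfinite(b)):
        raise ValueError("all bases must be positive and finite")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError("all values must be non-negative and finite")
    total = v.sum()
    if total <= 0:
        raise DegenerateCurveError("resource total is zero; shares undefined")
    order = np.argsort(v / b, kind="stable")
    x = np.concatenate([[0.0], np.cumsum(b[order]) / b.sum()])
    y = np.concatenate([[0.0], np.cumsum(v[order]) / total])
    x[-1] = 1.0
    y[-1] = 1.0
    if base_kind not in BASE_COLUMNS:
        raise ValueError(f"base_kind must be one of {sorted(BASE_COLUMNS)}")
    return LorenzCurve(np.column_stack([x, y]), base_kind, resource, year)


def gini(curve: LorenzCurve) -> GiniResult:
    """Gini coefficient of a Lorenz curve by the trapezoid formula.

    A tiny negative arising from floating error (|G| <= 1e-12) is clipped
    to zero.
    """
    x, y = curve.x, curve.y
    g = 2.0 * (0.5 - 0.5 * np.sum(np.diff(x) * (y[1:] + y[:-1])))
    if g < 0:
        if g < -1e-12:
            raise ValueError(
                f"negative Gini ({g!r}): curve is not ordered by per-base rate"
            )
        g = 0.0
    return GiniResult(value=float(g), band=classify_equity(g), n_regions=curve.n_regions)


def gini_from_values(values, bases) -> float:
    """Convenience: Gini of a raw allocation without building types."""
    return gini(lorenz_curve(values, bases)).value


def classify_equity(g: float) -> str:
    """Map a Gini coefficient to its equity band (lower edge inclusive)."""
    if not (0.0 <= g <= 1.0):
        raise ValueError(f"Gini coefficient must lie in [0, 1]; got {g}")
    for upper, label in EQUITY_BANDS:
        if g < upper:
            return label
    raise AssertionError("unreachable")


def gini_table(panel: Panel, resources=RESOURCES) -> pd.DataFrame:
    """Gini per (year, resource, base) — one row per year, 8 value columns.

    Each year is computed independently (cross-sectional).  Columns carry a
    (base, resource) MultiIndex with base in {by_population, by_geography}.
    """
    rows = {}
    for year in panel.years:
        sl = panel.year_slice(year)
        entry = {}
        for base_kind, base_col in BASE_COLUMNS.items():
            for res in resources:
                curve = lorenz_curve(
                    sl[res].to_numpy(),
                    sl[base_col].to_numpy(),
                    base_kind=base_kind,
                    resource=res,
                    year=year,
                )
                entry[(f"by_{base_kind}", res)] = gini(curve).value
        rows[year] = entry
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "year"
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["base", "resource"])
    return table


def lorenz_curves_for_year(panel: Panel, year: int, resources=RESOURCES):
    """All Lorenz curves for one year: {(base_kind, resource): LorenzCurve}."""
    sl = panel.year_slice(year)
    out = {}
    for base_kind, base_col in BASE_COLUMNS.items():
        for res in resources:
            out[(base_kind, res)] = lorenz_curve(
                sl[res].to_numpy(),
                sl[base_col].to_numpy(),
                base_kind=base_kind,
                resource=res,
                year=year,
            )
    return out


def plot_lorenz(panel: Panel, years=None, resources=RESOURCES, path=None):
    """Panel figure of Lorenz curves: one row per year, population-base and
    geography-base columns, one curve per resource plus the equity diagonal.

    Returns the matplotlib Figure; writes to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    years = list(years) if years is not None else [panel.years[0], panel.years[-1]]
    fig, axes = plt.subplots(
        len(years), 2, figsize=(9, 4.2 * len(years)), squeeze=False
    )
    for i, year in enumerate(years):
        curves = lorenz_curves_for_year(panel, year, resources)
        for j, base_kind in enumerate(("population", "geography")):
            ax = axes[i][j]
            ax.plot([0, 1], [0, 1], "k--", lw=1, label="equity line")
            for res in resources:
                c = curves[(base_kind, res)]
                ax.plot(c.x, c.y, lw=1.2, label=res.replace("_", " "))
            ax.set_title(f"{year} — by {base_kind}")
            ax.set_xlabel(f"cumulative {base_kind} share")
            ax.set_ylabel("cumulative resource share")
            ax.set_aspect("equal")
            if i == 0 and j == 0:
                ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
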