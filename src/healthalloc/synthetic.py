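"""Synthetic region-year panels and DEA test sets with known ground truth.

The panel generator emulates the structure of a provincial health-resource
panel: around twenty prefecture-level regions observed over five years,
with near-uniform per-capita resource rates (low population-base Gini) but
heavily concentrated per-km² densities (high geography-base Gini), because
population density across regions spans orders of magnitude.

Rather than drawing per-capita rates independently — whose base-weighted
Gini at n ≈ 21 scatters far too widely around the nominal value — the
generator assigns rates as lognormal quantiles taken at the cumulative
base-share midpoints of a random region ordering, with the lognormal σ
calibrated by root-solve so the trapezoid Gini of the generated allocation
equals the target exactly.  Areas are then obtained by a short fixed-point
iteration so the same holds in the geography dimension.  The closed form
σ(G) = √2·Φ⁻¹((G+1)/2) for the Gini of a lognormal seeds the calibration.

DEA test sets plant known radial efficiencies: frontier DMUs are built on a
constant-returns linear technology (inefficient input mixes are cone
combinations of efficient ones, so the observed hull reproduces the true
frontier), and each DMU's inputs are inflated by 1/θ*; the measured
input-oriented CRS efficiency then equals the planted θ*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .panel import RESOURCES, SCHEMA, Panel

#: per-1,000-population resource levels typical of township-level care
DEFAULT_RATES_PER_1000 = {
    "beds": 1.3,
    "health_technicians": 1.2,
    "licensed_physicians": 0.48,
    "registered_nurses": 0.35,
}


def sigma_for_target_gini(g: float) -> float:
    """Lognormal σ whose population Gini is ``g``: σ = √2·Φ⁻¹((g+1)/2)."""
    if not 0.0 <= g < 1.0:
        raise ValueError(f"target Gini must lie in [0, 1); got {g}")
    return float(np.sqrt(2.0) * norm.ppf((g + 1.0) / 2.0))


def gini_of_lognormal_sigma(sigma: float) -> float:
    """Inverse of :func:`sigma_for_target_gini` (closed form 2Φ(σ/√2) − 1)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float(2.0 * norm.cdf(sigma / np.sqrt(2.0)) - 1.0)


@dataclass(frozen=True)
class UtilizationLink:
    """Output coefficients tying service volumes to resource stocks."""

    consultations_per_technician: float = 1300.0
    admissions_per_bed: float = 14.0
    noise_sigma: float = 0.08  # multiplicative lognormal, keeps outputs > 0


@dataclass(frozen=True)
class SyntheticPanelParams:
    """Generating conditions for a synthetic region-year panel."""

    n_regions: int = 21
    years: tuple[int, ...] = (2017, 2018, 2019, 2020, 2021)
    seed: int = 0
    target_gini_population: float = 0.15
    target_gini_geography: float = 0.65
    mean_rate_per_1000: dict = field(
        default_factory=lambda: dict(DEFAULT_RATES_PER_1000)
    )
    population_range: tuple[float, float] = (4e5, 1e7)
    area_range: tuple[float, float] = (4e3, 1.5e5)
    annual_growth: float = 0.02
    utilization_link: UtilizationLink = field(default_factory=UtilizationLink)
    equal_bases: bool = False

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("n_regions must be at least 2")
        for name in ("target_gini_population", "target_gini_geography"):
            g = getattr(self, name)
            if not 0.0 <= g < 1.0:
                raise ValueError(f"{name} must lie in [0, 1); got {g}")
        for name in ("population_range", "area_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be positive with lo <= hi")
        if not self.years:
            raise ValueError("at least one year is required")


# -- calibrated Lorenz construction ---------------------------------------


def _trapezoid_gini(values: np.ndarray, bases: np.ndarray) -> float:
    # internal copy of the trapezoid Gini, kept separate from the equity
    # module so generator calibration and analysis stay independent paths
    r = values / bases
    o = np.argsort(r, kind="stable")
    v, b = values[o], bases[o]
    x = np.concatenate([[0.0], np.cumsum(b) / b.sum()])
    y = np.concatenate([[0.0], np.cumsum(v) / v.sum()])
    return float(1.0 - np.sum(np.diff(x) * (y[1:] + y[:-1])))


def _quantile_rates(bases_rank_order: np.ndarray, sigma: float) -> np.ndarray:
    """Lognormal quantiles at cumulative-base-share midpoints (ascending)."""
    w = bases_rank_order / bases_rank_order.sum()
    t = np.cumsum(w) - w / 2.0
    return np.exp(norm.ppf(t) * sigma)


def calibrated_rates(
    bases: np.ndarray, rank_perm: np.ndarray, target_gini: float
) -> np.ndarray:
    """Per-region rates whose base-weighted trapezoid Gini is exactly
    ``target_gini``, ascending along ``rank_perm``."""
    b_ord = np.asarray(bases, dtype=float)[rank_perm]
    if target_gini <= 1e-12:
        rates_ord = np.ones_like(b_ord)
    else:
        def gap(sigma: float) -> float:
            r = _quantile_rates(b_ord, sigma)
            return _trapezoid_gini(r * b_ord, b_ord) - target_gini

        hi = max(2.0 * sigma_for_target_gini(target_gini), 1.0)
        while gap(hi) < 0 and hi < 64.0:
            hi *= 2.0
        sigma = brentq(gap, 1e-10, hi, xtol=1e-13)
        rates_ord = _quantile_rates(b_ord, sigma)
    rates = np.empty_like(b_ord)
    rates[rank_perm] = rates_ord
    return rates


def _areas_for_target(
    counts: np.ndarray,
    rank_perm: np.ndarray,
    target_gini: float,
    geo_mean_area: float,
    max_iter: int = 200,
) -> np.ndarray:
    """Areas such that the area-weighted Gini of counts/area hits the
    target; fixed point on (area shares → density quantiles → areas)."""
    area = np.full_like(counts, geo_mean_area)
    for _ in range(max_iter):
        dens = calibrated_rates(area, rank_perm, target_gini)
        new_area = counts / dens
        new_area *= geo_mean_area / np.exp(np.mean(np.log(new_area)))
        if np.allclose(new_area, area, rtol=1e-13, atol=0.0):
            return new_area
        area = new_area
    return area


# -- panel generation ------------------------------------------------------


def generate_panel(params: SyntheticPanelParams) -> Panel:
    """Generate a complete, validated panel under the given conditions.

    Every resource-year allocation hits the population-base Gini target
    exactly, and the geography-base target likewise, because all resources
    share one latent regional ranking (regions keep their relative standing
    across resources and years, as real prefecture panels do) and counts
    across resource-years differ only by scale and a common growth factor.
    Utilization outputs are noisy monotone functions of the resource
    stocks.  Fully deterministic under ``seed``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_regions
    if p.equal_bases:
        pop = np.full(n, float(np.sqrt(p.population_range[0] * p.population_range[1])))
    else:
        pop = np.exp(
            rng.uniform(np.log(p.population_range[0]), np.log(p.population_range[1]), n)
        )
    rank_pop = rng.permutation(n)
    rank_geo = rng.permutation(n)
    base_rate = calibrated_rates(pop, rank_pop, p.target_gini_population)
    base_counts = base_rate * pop / 1000.0
    gm_area = float(np.sqrt(p.area_range[0] * p.area_range[1]))
    if p.equal_bases:
        area = np.full(n, gm_area)
    else:
        area = _areas_for_target(base_counts, rank_geo, p.target_gini_geography, gm_area)

    link = p.utilization_link
    region_ids = [f"R{i+1:02d}" for i in range(n)]
    rows = []
    for yi, year in enumerate(sorted(p.years)):
        growth = (1.0 + p.annual_growth) ** yi
        counts = {
            res: base_counts * p.mean_rate_per_1000[res] * growth
            for res in RESOURCES
        }
        u_noise = np.exp(
            rng.normal(-0.5 * link.noise_sigma**2, link.noise_sigma, size=(2, n))
        )
        consultations = (
            link.consultations_per_technician * counts["health_technicians"] * u_noise[0]
        )
        admissions = link.admissions_per_bed * counts["beds"] * u_noise[1]
        for i in range(n):
            rows.append(
                {
                    "region_id": region_ids[i],
                    "year": year,
                    "population": pop[i],
                    "area_km2": area[i],
                    "beds": counts["beds"][i],
                    "health_technicians": counts["health_technicians"][i],
                    "licensed_physicians": counts["licensed_physicians"][i],
                    "registered_nurses": counts["registered_nurses"][i],
                    "consultations": consultations[i],
                    "admissions": admissions[i],
                }
            )
    return Panel(pd.DataFrame(rows, columns=SCHEMA))


# -- DEA sets with planted efficiencies ------------------------------------


@dataclass(frozen=True)
class DEASyntheticSpec:
    """Conditions for a DEA test set with known radial efficiencies."""

    planted_thetas: tuple[float, ...]
    m_inputs: int = 4
    s_outputs: int = 2
    seed: int = 0
    technology: str = "crs_linear"  # or "vrs_power"
    returns_exponent: float = 0.7  # vrs_power only; < 1 = diminishing returns

    def __post_init__(self):
        th = np.asarray(self.planted_thetas, dtype=float)
        if th.ndim != 1 or len(th) < 1:
            raise ValueError("planted_thetas must be a non-empty 1-d sequence")
        if np.any((th <= 0) | (th > 1)):
            raise ValueError("planted efficiencies must lie in (0, 1]")
        if not np.any(th >= 1.0):
            raise ValueError("at least one planted efficiency must equal 1")
        if self.technology not in ("crs_linear", "vrs_power"):
            raise ValueError(f"unknown technology {self.technology!r}")
        if self.m_inputs < 1 or self.s_outputs < 1:
            raise ValueError("need at least one input and one output")


@dataclass(frozen=True)
class DEASyntheticSet:
    """Generated envelopment data plus its ground truth."""

    inputs: np.ndarray  # (n_dmus, m)
    outputs: np.ndarray  # (n_dmus, s)
    dmu_labels: tuple[str, ...]
    planted_thetas: np.ndarray
    technology: str


def generate_dea_set(spec: DEASyntheticSpec) -> DEASyntheticSet:
    """Build a DEA data set whose input-oriented CRS efficiencies are known.

    ``crs_linear``: outputs are a fixed positive linear map of inputs
    (y = Cx), so every frontier DMU is CRS-efficient; inefficient DMUs use
    input mixes inside the cone of the efficient DMUs' mixes, which keeps
    the observed hull equal to the true frontier; inputs are then inflated
    by 1/θ*.  The measured overall efficiency equals θ* exactly (up to LP
    tolerance).

    ``vrs_power``: single aggregate technology y_r ∝ (w·x)^γ with γ < 1.
    All on-curve DMUs are VRS-efficient; oversized ones show scale
    inefficiency with decreasing returns.  Planted values still inflate
    inputs but are only guaranteed to be recovered under the piecewise
    hull approximately; use this mode for qualitative RTS structure.
    """
    rng = np.random.default_rng(spec.seed)
    th = np.asarray(spec.planted_thetas, dtype=float)
    n, m, s = len(th), spec.m_inputs, spec.s_outputs
    eff_idx = np.flatnonzero(th >= 1.0)

    if spec.technology == "crs_linear":
        mixes = np.exp(rng.uniform(0.0, np.log(10.0), size=(len(eff_idx), m)))
        scales = np.exp(rng.uniform(0.0, np.log(10.0), size=n))
        X0 = np.empty((n, m))
        X0[eff_idx] = mixes * scales[eff_idx, None]
        ineff = np.setdiff1d(np.arange(n), eff_idx)
        if len(ineff):
            w = rng.dirichlet(np.ones(len(eff_idx)), size=len(ineff))
            X0[ineff] = (w @ mixes) * scales[ineff, None]
        C = np.exp(rng.uniform(0.0, np.log(5.0), size=(s, m)))
        Y = X0 @ C.T
    else:  # vrs_power
        w = np.exp(rng.uniform(0.0, np.log(3.0), size=m))
        scales = np.exp(rng.uniform(np.log(0.3), np.log(8.0), size=n))
        base_mix = np.exp(rng.uniform(0.0, np.log(4.0), size=m))
        X0 = scales[:, None] * base_mix
        agg = X0 @ w
        out_mix = np.exp(rng.uniform(0.0, np.log(3.0), size=s))
        Y = np.power(agg, spec.returns_exponent)[:, None] * out_mix

    X = X0 / th[:, None]
    labels = tuple(f"DMU_{j}" for j in range(n))
    return DEASyntheticSet(X, Y, labels, th.copy(), spec.technology)
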