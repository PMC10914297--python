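# Methods

This note records the models implemented in `healthalloc`, the conventions
and numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Panel data model

One row per (region, year): population (persons), area (km²), four resource
counts (beds, health technicians, licensed/assistant physicians, registered
nurses) and two utilization counts (consultations, hospital admissions).
Counts are floats, not integers — yearbook series often report annual
averages — and validation enforces finiteness, non-negative counts and
strictly positive population and area. `(region, year)` pairs must be
unique; a *complete* panel contains every region × year exactly once, and
the DEA stages require completeness. Region display order follows first
appearance in the file; every analysis re-sorts internally, so input order
never changes a result (tested). The XLSX reader is an adapter that maps a
supplementary sheet's headers onto the canonical schema via a configurable
column mapping, and a helper merges a separate population/area file on
(region, year) for the case where demographics come from a different
yearbook than the resource series.

## Lorenz curves and Gini coefficients

For counts $v_i$ and base $b_i$, regions are ordered ascending by the
per-base rate $v_i/b_i$ **of the active base** — per-capita when the base is
population, per-km² when the base is geography. Ordering the geography curve
by the per-capita rate instead can produce a non-convex polyline and a
negative trapezoid sum, so the standard Lorenz construction (order by the
rate being plotted) is used for both dimensions. Ties keep input order; the
Gini value is provably unaffected by tie order (tested). Cumulative shares
$(X_i, Y_i)$ get $(0,0)$ prepended, and

$$G = 2\,[\,0.5 - \tfrac12 \textstyle\sum_i (X_i - X_{i-1})(Y_i + Y_{i-1})\,].$$

A floating-point residue in $[-10^{-12}, 0)$ is clipped to zero; a larger
negative raises, since it indicates an unordered curve. The trapezoid value
is checked in the tests against an independent oracle, the base-share-
weighted mean absolute difference $G = \sum_{ij} w_i w_j |r_i - r_j| / (2\mu)$,
to $10^{-10}$ on random instances. Equity bands are lower-edge inclusive:
$[0,0.2)$ absolute equity, $[0.2,0.3)$ relatively fair, $[0.3,0.4)$
basically reasonable, $[0.4,0.5)$ transitional, $[0.5,0.6)$ wide gap,
$[0.6,1]$ dangerous inequality. Each year is computed cross-sectionally.

## HRDI and W

HRDI is implemented as the geometric mean
$\sqrt{(v/p \cdot 1000)(v/a)}$ — the form that is homogeneous of degree one
in the count and unit-coherent; the bare product is available behind
`method="product"` for sensitivity checks only. The W standard is the
**province aggregate** (total count over total population and total area for
the same year and resource), not the unweighted mean of regional HRDIs:
the aggregate is the only construction under which a region shaped exactly
like the province scores $W = 1$ (asserted in tests). The unweighted-mean
alternative is available via `standard="mean"`. No claim is made that W
averages to 1 across regions. Reporting flags mark regions with all
$W < 1$ and all $W > 1.8$ across resource-years.

## DEA

Input-oriented envelopment with three frontiers: CRS ($\lambda \ge 0$), VRS
($\sum\lambda = 1$), NIRS ($\sum\lambda \le 1$). Phase 1 minimizes the
radial contraction $\theta$; phase 2 fixes $\theta$ and maximizes the sum of
input and output slacks (the ε-free two-phase construction — no
non-Archimedean constant to choose). LPs are solved with
`scipy.optimize.linprog(method="highs")`.

Numerical choices:

- **Conditioning.** Every input and output column is rescaled to mean one
  before solving (radial scores are units-invariant — tested); slacks are
  rescaled back to original units. This keeps the LPs well conditioned when
  consultation counts (~10⁵–10⁶) sit next to physician counts (~10²).
- **Tolerances.** `tol = 1e-6` on θ ties and on slack-zero tests in the
  rescaled units; solvers legitimately return 0.999999… for efficient
  units. θ is clamped to $(0, 1]$, and tiny solver noise is clamped so
  $\theta_{CRS} \le \theta_{NIRS} \le \theta_{VRS}$ holds exactly.
- **Returns to scale.** Constant when $|\theta_{CRS}-\theta_{VRS}| \le$ tol;
  otherwise decreasing when $|\theta_{NIRS}-\theta_{VRS}| \le$ tol, else
  increasing — the standard NIRS comparison.
- **Slack source.** Reported slacks come from the CRS phase 2 by default
  (`slack_frontier="vrs"` switches): under CRS reporting a technically
  efficient unit can still carry non-zero, scale-related slack, which is the
  convention the by-year report follows.
- **Degeneracy.** Optimal λ and the split of slack across variables can be
  solver-dependent under degeneracy; only θ, slack sums and the
  zero/non-zero pattern are treated as reproducible surfaces.

Two DMU schemes are exposed: `years_as_dmus_on_totals` (each year's province
totals are one DMU — the by-year report) and `regions_as_dmus_per_year`
(independent cross-sections with regions as DMUs — the by-region report).
A five-DMU-per-region alternative in six dimensions would make almost every
unit trivially efficient, which is why the per-region report uses
cross-sections. Efficiency status requires $\theta_{CRS} \ge 1-$tol *and*
all slacks zero within tolerance. Output orientation, super-efficiency,
Malmquist indices and bootstrap intervals are out of scope.

## Synthetic data

`generate_panel` emulates the structure the analysis assumes: ~21
prefecture-level regions over 5 years; populations log-uniform over
4×10⁵–10⁷; areas spanning roughly 4×10³–1.5×10⁵ km²; per-1,000-population
resource levels around 1.3 beds, 1.2 technicians, 0.48 physicians and 0.35
nurses (typical township-level care); utilization tied to stocks
(≈1,300 consultations per technician, ≈14 admissions per bed) with
multiplicative lognormal noise (σ = 0.08) so outputs stay positive; 2%
annual growth.

**Calibrated Gini targets.** Independent lognormal rate draws have a
base-weighted Gini whose sampling spread at n = 21 is far wider than the
targets are separated (measured by up-front simulation: min–max ≈ 0.46–0.84
for a nominal 0.65 over 50 seeds). The generator therefore assigns per-capita
rates as lognormal quantiles at the cumulative-base-share midpoints of a
random region ordering, with σ calibrated by root-solve (started from the
closed form σ(G) = √2·Φ⁻¹((G+1)/2), which is also exposed and tested by
Monte Carlo) so the trapezoid Gini of the generated allocation equals the
population-base target exactly; areas then come from a short fixed-point
iteration so the geography-base target is hit exactly as well, with the
geometric-mean area pinned to the configured range. All resources share one
latent regional ranking — regions keep their relative standing across
resources and years, as real prefecture panels do — so every resource-year
hits both targets. A target of zero reproduces a perfectly proportional
allocation with Gini exactly 0.

What this does **not** emulate: cross-resource rank reversals (a region
under-provided in beds but over-provided in nurses), temporal drift of
inequality within a panel, reporting noise, and any correlation between
population size and per-capita provision. Passing recovery tests therefore
show that the analysis stages measure what the generator planted, not that
real yearbook data are noise-free or rank-stable.

**Planted DEA efficiencies.** Under `crs_linear` technology, outputs are a
fixed positive linear map of inputs ($y = Cx$), which makes every frontier
DMU CRS-efficient; inefficient DMUs' input mixes are drawn inside the cone
of the efficient DMUs' mixes, so the observed hull reproduces the true
frontier; inflating each DMU's inputs by $1/\theta^\*$ then makes the
measured input-oriented CRS efficiency equal the planted $\theta^\*$ exactly
(up to LP tolerance — the end-to-end recovery test). The `vrs_power` mode
places DMUs on a concave single-ray technology $y \propto (w\cdot x)^\gamma$,
$\gamma < 1$, for qualitative scale-efficiency and returns-to-scale
structure; planted values there are only approximately recoverable because
the piecewise-linear hull under-spans a smooth curve.

## Pipeline and reporting

`run_all` writes each table twice: a display CSV rounded to the conventional
precision (2 decimals for Gini and W, 3 for efficiencies) and a `*_full.csv`
at machine precision; every displayed number is a pure rounding of its
machine-precision counterpart, and re-running with identical inputs is
byte-identical on the machine-precision outputs (both tested). Plots are
artifacts, not test surfaces; tests assert the plotted point sets.

## Problem sizes used in the checks

The automated checks run the generator at 21 regions (1 or 5 years as
needed), 50 seeds per Gini-target combination, 200 random instances for the
Gini oracle comparison, 100 for the DEA closed-form comparison, and planted
DEA sets of 5–21 DMUs with 4 inputs and 2 outputs — sizes matched to the
study design the package targets.

## Known limitations

- Only input orientation is implemented.
- The Gini is computed at the regional aggregation supplied; decomposition
  (Theil, concentration indices) is out of scope.
- The W standard and the HRDI radical are conventions with switches, not
  empirically identified choices; results should state which was used
  (the pipeline's metadata JSON records both).
- DEA efficiency is relative to the observed peer set: adding or removing a
  DMU can change every score, and slack values under degeneracy are
  solver-dependent (only θ and the slack pattern are stable).
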