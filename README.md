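# healthalloc

Equity and efficiency analysis of regional health-resource panels.

Health planners ask two distinct questions about how resources such as
hospital beds, health technicians, physicians and nurses are distributed
across the regions of a province. **Is the allocation equitable?** — are
resources spread in proportion to the people (or the territory) they serve?
**Is it efficient?** — do the resources deployed in a region, or a year,
produce as much service (consultations, admissions) as the best-performing
peers manage with comparable inputs? `healthalloc` implements the standard
toolkit for both questions as one tested pipeline over a simple region × year
CSV panel, together with a synthetic-data generator so every stage can be
exercised with known ground truth.

## Methods at a glance

**Lorenz curves and Gini coefficients.** For a resource with regional counts
$v_i$ and allocation base $b_i$ (population or geographic area), regions are
ranked ascending by the per-base rate $v_i/b_i$ and cumulative shares
$(X_i, Y_i)$ are accumulated, with $X_0 = Y_0 = 0$. The Gini coefficient is
twice the area between the curve and the diagonal, computed by the trapezoid
rule:

$$G = 2\left[\,0.5 - \tfrac{1}{2}\sum_{i=1}^{n}(X_i - X_{i-1})(Y_i + Y_{i-1})\right]$$

$G < 0.2$ is read as absolute equity, $0.2$–$0.3$ relatively fair,
$0.3$–$0.4$ basically reasonable, $\ge 0.5$ a wide gap and $\ge 0.6$ a
dangerous degree of inequality.

**Health resource density index (HRDI).** The geometric mean of the count
per 1,000 population and the count per km²,
$\mathrm{HRDI} = \sqrt{(v/p \times 1000)\,(v/a)}$, combines demographic and
geographic access in one number; the standardized index
$W = \mathrm{HRDI}_{\text{region}} / \mathrm{HRDI}_{\text{standard}}$
compares each region with the province aggregate, so $W > 1$ marks
above-average allocation.

**Data envelopment analysis (DEA).** Input-oriented envelopment LPs measure,
for each decision-making unit (a year's province totals, or a region within
a year), the largest equiproportional input contraction $\theta$ that a
convex combination of observed units could still dominate. The CRS (CCR)
score is the overall efficiency, the VRS (BCC) score the technical
efficiency, their ratio the scale efficiency; a second LP phase maximizes
residual slacks (the ε-free two-phase construction) and a CRS/NIRS/VRS
comparison classifies returns to scale. Inputs are the four resource counts,
outputs the two utilization counts.

## Worked example

```python
import healthalloc as ha

panel = ha.generate_panel(ha.SyntheticPanelParams(seed=42))
print(ha.gini_table(panel).round(2).to_string())
```

```
base     by_population                                ...  by_geography          ...
resource          beds health_technicians             ...          beds          ...
year
2017              0.15               0.15             ...          0.65          ...
2018              0.15               0.15             ...          0.65          ...
...
```

The generator was asked for a population-base Gini of 0.15 and a
geography-base Gini of 0.65 (the defaults), and the equity stage recovers
exactly those values for every resource and year: per-capita allocation in
the absolute-equity band, per-km² allocation in the dangerous-inequality
band — the typical signature of a province whose population density varies
by orders of magnitude across regions.

```python
res = ha.run_dea(panel, "years_as_dmus_on_totals")
print(res.summary(input_names=ha.RESOURCES, output_names=ha.UTILIZATION))
```

```
Input-oriented DEA, 5 DMUs, 4 inputs, 2 outputs; slacks from CRS phase 2, tol=1e-06
 dmu  overall_efficiency  technical_efficiency  scale_efficiency returns_to_scale ...      status
2017               0.988                 1.000             0.988       increasing ... inefficient
2018               1.000                 1.000             1.000         constant ...   efficient
2019               0.994                 0.996             0.997       decreasing ... inefficient
2020               0.997                 1.000             0.997       increasing ... inefficient
2021               1.000                 1.000             1.000         constant ...   efficient
```

Each year is a decision-making unit built from province totals. A year with
overall efficiency 1.000 and zero slacks is DEA-efficient: no convex
combination of the other years produced the same service volumes with
proportionally fewer resources. Where overall < technical the shortfall is
attributable to scale rather than technique.

The same analyses run from the shell:

```sh
healthalloc simulate --seed 42 --out panel.csv
healthalloc run-all --input panel.csv --out report/
```

which writes `gini_table.csv`, `w_table.csv`, `dea_by_year.csv`,
`dea_by_region.csv`, per-region density data, Lorenz plots and a
run-metadata JSON (each display table has a `*_full.csv` companion at
machine precision).

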