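# chronicost

Projection pipeline for the direct medical costs of a chronic disease (two
diagnosed diabetes types as the worked example): an illness-death-model PDE
carries age- and sex-specific prevalence from a 2010 baseline to 2040 under
scenario trends in incidence and the mortality rate ratio, and a coupled
cost model projects per capita costs, total and excess costs, cost ratios,
population attributable cost fractions and a national extrapolation across
16 deterministic scenarios.

Because the original demographic and claims inputs are not public, the
package ships a first-class synthetic-data module that generates all
pipeline inputs — a cohort-component population projection with six
demographic variants, calibrated epidemiological rate surfaces
(population-weighted base-year prevalence of ~7% type 2 and ~0.3% type 1)
and an aggregated claims-style cost table whose baseline per capita costs
land on published 2010 magnitudes.

## Layout

| module | purpose |
| --- | --- |
| `chronicost.synthetic_data` | population, epidemiology and cost-table generators |
| `chronicost.interpolation` | natural-spline and grouped-linear age interpolation |
| `chronicost.prevalence_projection` | illness-death PDE solver, trends, microsimulation oracle |
| `chronicost.cost_model` | per capita baselines, excess growth, totals, cost ratio R, PAC, extrapolation |
| `chronicost.scenarios` | the 16-scenario table and the end-to-end runner |
| `chronicost.cli` | `chronicost synth / run / summarize` |

## CLI

```bash
# generate synthetic inputs (one or all six demographic variants)
chronicost synth --variant G2L2W2 --seed 2010 --out inputs/

# run scenarios end to end; writes per-scenario result CSVs,
# summary.csv and a machine-readable run_log.json
chronicost run --inputs inputs/ --out results/ --scenarios 1,6,7,8,9,10,16

# re-print the summary table
chronicost summarize --results results/
```

`run` accepts a YAML config (`--config`) with `pde_step`,
`sample_fraction` and per-scenario field overrides, e.g.

```yaml
pde_step: 0.25
scenarios:
  2: {incidence_trend: 0.015}
```

Scenario semantics: 1 is the base case (MRR −2%/yr only), 2–7 vary the
incidence trend (±1/±2/±5 %/yr), 8 holds prevalence constant at the 2010
cross-section, 9/10 apply 1%/5% annual excess-cost growth, 11–15 vary the
demographic variant, and 16 combines +1% incidence, −2% MRR and 1% cost
growth.

## Python API

```python
from chronicost import build_scenarios, default_inputs, run_scenario

inputs = default_inputs(seed=2010)
spec = {s.id: s for s in build_scenarios()}[16]
result = run_scenario(spec, inputs)
result.annual_totals("T2")        # euro per year, summed over sexes
result.aggregate                  # attributable fractions + national euro
```

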