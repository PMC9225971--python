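# deerflux

Annual nitrogen and phosphorus budgets for semi-natural open habitats grazed
by wild ungulates, computed from dung and vegetation survey records.

Protected low-nutrient habitats such as dry heaths and lowland hay meadows
are threatened by atmospheric nutrient deposition. Free-ranging large
herbivores move nutrients in and out of these habitats: they import N and P
in dung (and N in urine) and export both by grazing. `deerflux` turns raw
field records — pellet-group counts on cleared plots, dung decay trials,
pellet-group dry masses, plant and faecal N/P concentrations, and forage
removal from grazing-exclusion cages — into per-period fluxes and annual
habitat budgets with propagated uncertainty, and weighs the net balance
against atmospheric deposition scenarios. It ships with a synthetic survey
generator whose expected budget is known in closed form, so the entire
pipeline is testable without any field data.

## The model

**Dung accumulation.** Pellet groups are counted on cleared plots at each
sampling date (faecal accumulation rate method). Some groups decay before
the recount; a site- and period-specific decay experiment gives the lost
fraction *r*, and since deposition times are roughly uniform within a period
(mean exposure of half a period), the corrected count is

```
pg_cor = pg_obs / (1 − r/2)
```

Dung dry mass per hectare follows from `pg_cor`, the site × date mean
pellet-group dry mass, and the plot area (225 m² by default).

**Fluxes.** With concentrations in % of dry mass (period value = mean of the
start- and end-date concentrations, with documented imputation of missing
endpoints),

```
faecal import = dung mass × conc/100        export = forage removal × conc/100
```

Urinary N is not measured in dung surveys; it is estimated from the ratio of
urinary to faecal N excretion, a function of dietary N (fraction of DM) and
metabolic body mass w^0.75 (w = 100 kg for red deer):

```
U_ratio = (11.56·pN + 0.004/(pN·w^0.75) + 0.078) / (0.05 + 0.00421/pN)
N_total = faecal N · (1 + U_ratio)
```

Urinary P is zero (P is excreted almost exclusively in dung).

**Annual budgets.** Per habitat, each period's flux is summarised over plots
(mean, SE = SD/√n); the annual rate is the sum of period means with Gaussian
error propagation, `se = √Σ se_i²`, and 95% CI = mean ± 1.96·se. The net
balance Δ = import − export (negative Δ: the habitat loses nutrients to
grazing); a deposition scenario reports `deposition + Δ`, conservatively
`deposition + CI_upper(Δ)`.

## Worked example

```python
import deerflux as dx

# a study-like synthetic survey: 2 habitats x 4 sites x 2 plots x 5 periods
ds = dx.generate(dx.default_config(), seed=1)
budget = dx.annual_budget_table(dx.flux_table(ds))
print(budget.round(2).to_string(index=False))
```

```
  habitat        variable   mean   se  ci_lo  ci_hi
heathland faecal_N_import   2.59 0.23   2.13   3.05
heathland  total_N_import   4.14 0.37   3.42   4.86
heathland        N_export  19.98 1.60  16.84  23.13
heathland        P_import   0.34 0.03   0.29   0.39
heathland        P_export   1.80 0.12   1.56   2.04
heathland         delta_N -15.84 1.65 -19.07 -12.61
heathland         delta_P  -1.46 0.13  -1.71  -1.21
grassland faecal_N_import   2.64 0.20   2.25   3.04
grassland  total_N_import   4.94 0.38   4.20   5.67
grassland        N_export  33.07 2.86  27.46  38.68
grassland        P_import   0.74 0.06   0.63   0.85
grassland        P_export   4.31 0.37   3.59   5.03
grassland         delta_N -28.13 2.89 -33.79 -22.47
grassland         delta_P  -3.57 0.37  -4.30  -2.84
```

All rates are kg ha⁻¹ a⁻¹. Both habitats show a strongly negative net N and
P balance: grazing removes far more than excreta return, most markedly in
the productive grassland. Weighing the heathland ΔN against an atmospheric
deposition of 11 kg N ha⁻¹ a⁻¹:

```python
row = budget.set_index(["habitat", "variable"]).loc[("heathland", "delta_N")]
delta = dx.AnnualRate(row["mean"], row["se"], row["ci_lo"], row["ci_hi"])
sc = dx.deposition_scenario(delta, 11.0)
print(round(sc.net_input, 2), round(sc.conservative_net_input, 2))
# -4.84 -1.61
```

so even the conservative upper CI limit leaves a net N removal for this
simulated survey. The same operations applied to the published annual rates
(import 4.91, export 18.81, CIs [3.81, 6.01] and [9.91, 27.71]) give
Δ = −13.90 with CI [−22.87, −4.93] and a conservative net input of 6.07 kg
N ha⁻¹ a⁻¹ at 11 kg deposition.

A command-line interface wraps the same pipeline:

```
deerflux simulate --seed 3 --out survey/
deerflux validate survey/
deerflux budget --input survey/ --deposition 11 --out results/
deerflux truth
```

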