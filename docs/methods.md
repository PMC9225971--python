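# Methods

This note documents the models, conventions and design choices behind
`deerflux`, what its synthetic data generator does and does not emulate, and
the package's known limitations.

## Survey design and data model

The shipped default design is a one-year survey of two habitat types
(heathland, grassland) × four sites × two management treatments (burnt B,
untreated U), sampled at six dates bounding five consecutive periods that
cover exactly one year (Apr–May, May–Jun, Jun–Aug, Aug–Oct, Oct–Apr).
Vegetation data are plot-level (16 plots of 15 × 15 m); dung is recorded on
one plot adjoining each B plot and on two subplots on opposing sides of each
U plot, which are averaged into a single U record, giving 4 sites × 2 plots
× 2 habitats × 5 periods = 80 observations per response variable. All of
this — habitats, sites, treatments, dates, plot area — is configurable; the
study layout is only the default.

All tables are long-format delimited text with an empty cell as the missing
marker. Missingness is preserved through every stage: a missing value never
becomes zero, and summaries count only non-missing plots. Pellet groups
lying on a plot edge are counted as inside; no edge correction is applied.

## Dung decay correction

The decay experiment places marked fresh pellet groups per site and date
(five by default) and records, at the next date, how many have decayed (a
group with fewer than six pellets retrieved counts as lost), giving a lost
fraction `r = n_lost / n_placed` per site × period. Counts accumulated over
a period are corrected as `pg_cor = pg_obs / (1 − r/2)`. The factor r/2
reflects uniform deposition times: a group deposited at a uniform moment in
the period is exposed to decay for half the period on average, so the
expected detection probability is 1 − r/2. The matched simulation oracle in
the test suite (event-level deposition and decay) confirms the estimator
recovers the true deposited count.

Fallbacks when a site's trial is missing: the habitat × period mean of the
other sites' trials, then r = 0 with a warning (the conservative choice — an
uncorrected count assumes no decay). `pg_cor` is kept as a real number,
never rounded, because it feeds continuous mass arithmetic. A marked group
replaced mid-winter is treated as a fresh trial from its placement date;
the ingest schema simply takes `n_placed`/`n_lost` as recorded.

Mean pellet-group dry mass is the site × date arithmetic mean of the
collected groups (five by default), with a habitat × date mean as fallback;
the mass used for a period is that of the period's **end** date, the date at
which the accumulated dung was counted. If one U subplot's record is missing
for a period, the U value for that period is missing, not halved — averaging
over unequal exposure would bias the mass estimate.

## Concentrations and forage removal

Concentrations are % of dry mass, validated to (0, 100). Plant samples are
plot-level hand-plucks (upper third of the sward, a diet proxy); faecal
samples are site-level and broadcast to both plots of the site. The period
value is the mean of the start- and end-date concentrations; a missing
endpoint is imputed with the habitat × date mean before averaging, and the
first survey date — which has no plant sampling — borrows the same plot's
value from the matching date one year later. Every period value carries a
provenance label (`measured_both_ends`, `imputed_one_end`,
`imputed_both_ends`, `substituted_apr2016`); imputation never overwrites a
measured cell.

Forage removal is the difference in biomass increment between vegetation
temporarily protected by a movable exclusion cage and the adjacent grazed
sward. Negative values (measurement noise) are retained and flagged, not
truncated: truncation would bias annual export upward, and the flag lets
users reproduce either convention. Standing biomass can be obtained from
rising-plate sward heights through a linear least-squares calibration
against cut quadrats (fitted per habitat by default, ≥ 3 pairs required);
plots without a usable calibration (the burnt heathland plots in the default
design) have structurally missing removal and are omitted listwise from
export summaries.

## Urinary nitrogen model

Dung surveys cannot measure urine, so urinary N import is estimated from the
ratio of urinary to faecal N excretion,

U_ratio = (11.56 pN + 0.004/(pN·w^0.75) + 0.078) / (0.05 + 0.00421/pN),

with dietary N concentration pN as a *fraction* of dry matter and body mass
w = 100 kg by default (adult red deer); total N import is faecal N × (1 +
U_ratio). The public interfaces take concentrations in %, and the model
converts internally; passing a percent value where a fraction is expected
changes the result by orders of magnitude, so inputs above 0.1 trigger a
warning. U_ratio increases with dietary N and decreases with body mass (only
through the w^0.75 term); its low-diet limit is 0.004/(w^0.75·0.00421) ≈
0.030 at w = 100. It is evaluated per observation period at the habitat ×
period mean plant N — evaluating at annual mean diets instead gives slightly
lower values (0.642 vs ≈ 0.65 at pN = 0.01307), the usual Jensen gap between
a mean of ratios and a ratio at the mean. Urinary P is fixed at zero, and
urine is assumed to follow the spatial pattern of defecation.

## Annual budgets and uncertainty

Per habitat × period × variable, plots are pooled across both treatments
(treatments exist for the sampling layout, not as a factor of interest) and
summarised as mean and SE = SD/√n; a single observation yields SE 0 with a
warning. Annual rate = Σ period means; SE by Gaussian error propagation
√Σ se², treating periods as independent; 95% CI = mean ± z·se with z = 1.96
(the normal quantile — this convention reproduces published budget-table CIs
exactly when SEs are back-computed from them, which is also how the
`se_from_ci` helper is meant to be used). The net balance Δ = import −
export with SE √(se_i² + se_e²). An annual rate is undefined (an error, not
a silent NaN) if any period summary is entirely missing. Reported rounding:
two decimals for budgets, one for N:P ratios.

Deposition scenarios report `net_input = deposition + Δ` and a conservative
variant using the upper CI limit of Δ, i.e. the smallest net export
compatible with the data. `fraction_of_production` relates |net removal| to
the nutrient pool in annual aboveground biomass.

## Synthetic survey generator

The generator (`deerflux.synthetic`) emulates the survey's statistical
structure with an analytically known expected budget:

- pellet-group deposition per dung plot × period: negative binomial
  (habitat-specific dispersion; field counts are overdispersed, more so in
  heathland), Poisson when no dispersion is set;
- detection thinning: each deposited group is observed with probability
  1 − r_true/2, the same uniform-deposition-time argument the correction
  inverts, making `correct_pellet_count` the matched estimator;
- decay trials: binomial(n_placed, r_true) per site × period;
- pellet-group masses: lognormal (mean 32.4/29.9 g, CV 0.30);
- concentrations: normal, truncated to (0, 100) by redraw, site- or
  plot-level as in the real protocol;
- forage removal: normal per plot × period;
- missingness: per-variable Bernoulli (defaults: faecal concentrations 0.15,
  others 0.05), plus the two structural gaps of the study — no plant samples
  at the first date, and no forage data on two burnt heathland plots.

The shipped default configuration targets the magnitude and seasonality of
the study system: winter-heavy heathland dung (period deposition means 12,
12, 15, 15, 53.5 groups/plot; annual dung ≈ 155 kg ha⁻¹) versus summer-heavy
grassland dung (15, 16, 17, 16, 9; ≈ 97 kg ha⁻¹), date-level concentration
means averaging to plant N 1.31/1.63%, plant P 0.117/0.217%, faecal N
1.91/2.73% and faecal P 0.24/0.79% (heathland/grassland), and removal means
giving annual N exports near 19/34 kg ha⁻¹. Plot-level SDs are
back-of-envelope reconstructions (SD ≈ SE·√n from habitat-level summary
statistics), not measured quantities. All draws flow through one seeded
generator in a fixed documented order, so a seed fully determines a dataset.

`true_budget` gives the closed-form expectation of every budget component:
expected corrected count equals the deposition mean (thinning at 1 − r/2 is
exactly undone by the correction), and imports/exports are products of
configured means summed over periods, with U_ratio at the period mean plant
N. A deterministic-counts mode (deposition = rounded mean, expected
thinning) supports an exact identity test: with all SDs, missingness and
decay at zero, the full pipeline reproduces the true budget to machine
precision (observed max |error| ≈ 9e-16).

What the generator does **not** emulate: spatial structure within plots,
temporal autocorrelation across periods, treatment effects on vegetation,
animal movement or density, between-year variation, and nutrient losses
from excreta (volatilisation, leaching). Tests passing on synthetic data
therefore validate the accounting pipeline and its uncertainty arithmetic,
not the field protocol itself.

## Calibration of the propagated uncertainty

A 200-replicate recovery study at the default (study-like) settings, run in
the acceptance suite, shows the pipeline estimators are unbiased (|relative
bias| ≤ 1.4% for every budget component) and that the 95% CIs cover the true
exports and net balances in 94–96% of replicates. Import components cover at
only 83–90%: faecal concentrations, pellet-mass means and decay rates are
sampled at site level and shared by the two plots of a site, so the eight
plot values per habitat × period are pairwise correlated and the plot-wise
SD/√n underestimates the SE of their mean (propagated-SE/empirical-SD ratio
0.75–0.86 for imports). This is a property of the survey design combined
with the standard independent-observation propagation, not of the
implementation; export variance is dominated by independent plot-level
forage noise and is essentially nominal, and the net balances — the
quantities the deposition scenarios use — inherit the export's good
coverage. Users who need calibrated import CIs should summarise at site
level (n = 4) or bootstrap sites.

## Numerical choices

- Numeric file parsing uses exact Python `float` conversion so that write →
  read round-trips are bit-for-bit, including missing markers.
- Truncated-normal concentration draws use rejection with a clip fallback
  after 100 attempts (irrelevant at the shipped means, which sit many SDs
  from the bounds).
- `annualize` is permutation-invariant in period order; seeds derived for
  sub-tasks stay below 2³¹.
- Problem sizes in the test and acceptance suites: 200 recovery replicates,
  60 decay-trial replicates, 10⁵ Monte-Carlo draws for the error-propagation
  oracle, 4 000 event-level decay simulations — sizes chosen to put
  Monte-Carlo error well below the tolerances they check.

## Known limitations

- The nutrient balance covers excretal import and grazing export only: no
  volatilisation, leaching, N₂ fixation, carcasses/antlers, or harvest
  export; the urinary model inherits the hand-pluck diet proxy.
- Import CIs are anti-conservative under site-level sampling (see above).
- The decay correction assumes uniform deposition times within a period and
  a constant within-period decay hazard; strongly pulsed deposition would
  bias it.
- `np_export_ratio` is reported as a magnitude ratio and is meaningful only
  when both net balances have the same sign.
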