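# Methods

## Scope and structure

`ddtexpo` estimates nonoccupational ΣDDT exposure for four populations
(TGP, THEP, NGP, NHEP) in five stages: distribution fitting
(`concentration_db`), route-specific uptake (`uptake_routes`), Monte
Carlo convolution (`exposure_engine`), steady-state pharmacokinetics
(`pk_model`), and biomonitoring evaluation (`biomonitoring_eval`), with a
synthetic scenario generator (`synthetic_data`) and an orchestration/CLI
layer (`reporting`, `cli`).

## Distribution fitting

Inputs are study-level central values (means or medians pooled as one
observation class — an acknowledged approximation, since the two
statistics coincide only for symmetric within-study distributions). Each
central value counts as a single log-scale observation, unweighted by the
number of underlying measurements; for a lognormal this makes `mu` the
mean of the logs (the MLE) and `sigma` the sample standard deviation
(n−1 denominator, chosen so results are deterministic and unbiased at
small n). One observation yields a point mass (`sigma = 0`). Whether
fitting study summaries or underlying individuals is the better reading
of the source assessments is unresolved; fitting summaries is the only
option available when individual data are unpublished, and is what this
package does. Indoor soil/dust carries too few values for a lognormal and
is represented by a bounding uniform from the minimum to the maximum of
the reported values.

## Uptake equations and exposure factors

All routes are linear in concentration and use point-estimate exposure
factors, so concentration variability is deliberately the only source of
variability in the output: the assessment converts literature variability
into uptake ranges rather than modeling inter-individual variability.

Key parameters (units, default, origin):

| parameter | units | default | note |
|---|---|---|---|
| E_diet | – | 0.9 | gastrointestinal uptake efficiency |
| E_gas / E_particle | – | 1 / 0.44 | inhalation efficiencies; a generic 0.75/0.75 variant is a config switch |
| V_inh | m³/day | 15 | generic adult inhalation rate (assumption, configurable) |
| indoor fraction (THEP) | – | 8/24 | time indoors in IRS dwellings |
| SDA | mg/cm² | 1 | soil/dust adherence (conservative) |
| AE | cm² | 1,120–9,550 | exposed skin, feet only → full extremities |
| UR_derm | 1/day | 0.01 | dermal uptake rate constant (assumption, configurable) |
| ADI | µg/kg/day | 20 | threshold = ADI·65 kg·1000 = 1.3e6 ng/day |

Populations other than the THEP assume indoor air equals outdoor air, in
which case inhalation collapses to `V_inh·C_out·E_gas` and the time split
is irrelevant. A steady-state well-mixed box model
(`indoor_air_mass_balance`) provides an order-of-magnitude screen for
indoor IRS air from a wall-evaporation flux.

## Monte Carlo design

Default 2,000 iterations. Media are sampled independently within an
iteration (no cross-media correlation is asserted by the source data).
Each medium draws from its own substream whose seed is derived
deterministically from the run seed and the medium label (CRC32 mix,
reduced mod 2³¹), so omitting one route leaves the other routes' draws
bit-identical — route-omission factors are therefore exact contrasts, not
re-randomizations. The total column is the exact row-wise sum of the
route columns. Percentiles use linear interpolation between order
statistics (numpy's `linear` method), fixed and documented because
results at the 5th/95th percentile depend visibly on the rule at n =
2,000. Route shares are ratios of medians (median route over median
total), not medians of ratios; they need not sum to exactly 100%. The
per-iteration alternative is available by operating on the samples
directly.

## Pharmacokinetics

Steady state of a one-compartment model: uptake balances first-order
elimination, `C = U·t½(days)/ln2/(M_lipid·1000)` in ng/g lipid. The
dose-weighted half-life combines the intrinsic half-lives of p,p′-DDT
(2.2 y) and p,p′-DDE (6.2 y) by adding their first-order rate constants
weighted by the intake composition — the physically motivated rule for
parallel elimination of co-ingested components. At a DDE:DDT intake ratio
of 2.7 this gives 4.16 y; published THEP-type assessments quote 4.1 y,
the small difference presumably reflecting an intake composition or
weighting convention not fully specified in print. An arithmetic
half-life average is available behind the `weighting="arithmetic"` flag
for sensitivity analysis. Body lipid mass defaults to 16.25 kg (65 kg ×
0.25 lipid fraction), configurable and echoed into every report's
assumption block. Because the uptake→concentration map is monotone,
concentration percentiles equal the map applied to uptake percentiles;
the implementation applies it per sample and the property is tested.

Intake DDE:DDT ratios are taken from the biomonitoring window medians
when records are available (the body ratio is the best available proxy
for the intake ratio at steady state), else from configured defaults
(8.5 TGP, 2.7 THEP, 9.0 NGP, 8.0 NHEP).

## Biomonitoring evaluation

Study-level medians, unweighted by group size (n-weighting would let a
single large cohort dominate a literature median; it can be added via the
record frame if wanted). Decline rates come from OLS of ln(ΣDDT) on year
(statsmodels), reported as the negative slope with its 95% CI. ANOVA
contrasts are computed on natural logs by default since both levels and
ratios are analyzed on log scales; a raw-scale option exists. The
model-vs-measured agreement factor is `max/min ≥ 1`, flagged consistent
below 2. The default comparison window is 1995–2008, matching the
exposure-media period.

## Synthetic scenario

The generator emulates the statistical structure of the literature
database, calibrated only to published contrasts, not to the underlying
supplementary tables: indoor IRS gas-phase air median 4 µg/m³ (within the
reported 1–10 µg/m³), exactly 10³ × the tropical outdoor median (4 ng/m³)
and 10⁶ × the northern outdoor median (0.004 ng/m³); DDE:DDT ratio
anchors 8.5 (TGP, growing) and 2.7 (THEP, flat); food-group medians and
consumption baskets chosen so diet dominates the general and Inuit
populations while indoor inhalation dominates the IRS population.
Biomonitoring level anchors are set near the steady-state concentrations
the PK model implies for the scenario's uptake, making the synthetic
world internally consistent — the model-vs-measured factor on synthetic
data therefore verifies pipeline correctness, not real-world model skill.
Levels decline first-order with lognormal noise (σ = 0.3), sparse
sampling before 1993 and denser after, mimicking literature availability.

What the generator does **not** emulate: between-study heterogeneity in
analytical method, congener coverage and matrix; correlation between food
groups; exposure-factor variability; non-stationary IRS spraying
schedules. Green tests on synthetic data show the machinery is correct
under the stated assumptions, not that those assumptions hold in any
particular region.

## Numerical choices and degenerate inputs

Zero-sigma lognormals and equal-bound uniforms are exact point masses
(no jitter). Fitting rejects non-positive concentrations by naming the
offending record; mixed media cannot be pooled. Decline fits require ≥ 3
records over ≥ 2 distinct years; ANOVA requires ≥ 2 positive values per
group; route shares and omission factors reject a zero median total.
Seeds derived from the run seed stay below 2³¹.

## Problem sizes

Default runs use 2,000 Monte Carlo iterations per population; the
closed-form Monte Carlo check uses 100,000 iterations; parameter-recovery
checks use 200 synthetic summaries and 500 decline-rate replicates of 30
years each. These sizes give sampling error comfortably below the
tolerances asserted in the tests.

## Known limitations

No exposure-factor variability; no dust ingestion, clothing-mediated
dermal exposure, or contamination of food stored in dwellings; no
breast-milk transfer or age-resolved pharmacokinetics; no meta-analytic
heterogeneity weighting; ΣDDT is modeled as a two-component mixture
(DDT/DDE) for elimination only.
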