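# ddtexpo

Geographically integrated, probabilistic assessment of nonoccupational
human exposure to DDT and its metabolites (ΣDDT = p,p′-DDT + p,p′-DDE +
p,p′-DDD).

## The problem

DDT remains in use for indoor residual spraying (IRS) against malaria
vectors, while long-range transport and bioaccumulation expose people far
from any application. `ddtexpo` compares four populations — the tropical
general population (TGP), people living in IRS-treated dwellings (THEP),
the northern general population (NGP), and marine-mammal-consuming Inuit
(NHEP) — by converting the variability of reported ΣDDT concentrations in
exposure media into distributions of daily uptake and lipid-normalized
body concentration, which can then be confronted with biomonitoring data.
It is aimed at exposure scientists and risk assessors working with
study-level literature summaries rather than individual measurements.

## The model

Study-level concentration summaries per medium are fitted with lognormal
distributions (uniform bounds for sparse indoor soil/dust). Route-specific
daily uptake (ng/person/day) uses three multiplicative equations with
point-estimate exposure factors:

- diet: `U_diet,i = m_i · f_lipid,i · C_i · E_diet` (E_diet = 0.9),
  summed over food groups;
- inhalation: `U_inh = V_inh · [(1−f_in)·C_out·E_gas + f_in·(C_in,gas·E_gas
  + C_in,part·E_part)]` with E_gas = 1 and E_part = 0.44; all populations
  except the THEP assume indoor air equals outdoor air;
- dermal (IRS dwellings only): `U_derm = SDA · AE · C_sd · UR_derm`,
  bounded between minimal (feet only, AE = 1,120 cm²) and maximal
  (extremities, AE = 9,550 cm²) parameter products and sampled uniformly.

Per Monte Carlo iteration (default 2,000) one value is drawn from each
medium's distribution and the routes are summed; total uptake is the
convolution of the route distributions. A steady-state one-compartment
pharmacokinetic model translates each total-uptake sample into a body
concentration, `C = U · t½ / ln2 / M_lipid`, using a dose-weighted
elimination half-life that combines the intrinsic half-lives of p,p′-DDT
(2.2 y) and p,p′-DDE (6.2 y) according to the population's DDE:DDT intake
composition. Biomonitoring records are summarized with first-order decline
fits of ln(ΣDDT) on year, DDE:DDT ratio medians, and log-scale ANOVA
contrasts; modeled and measured medians are compared through a symmetric
agreement factor (consistent when < 2).

A seeded synthetic-data module generates concentration summaries and
biomonitoring series with the structure the analysis assumes (indoor IRS
air ≈ 10³ × tropical and ≈ 10⁶ × northern outdoor air; declining,
noisy biomonitoring series; ratio trajectories flat only for the THEP),
so the whole pipeline runs and is tested without any data download.

## Worked example

```python
from ddtexpo import RunConfig, run_pipeline

report = run_pipeline(RunConfig(n_iter=2000, seed=1))
for pop, entry in report["populations"].items():
    p = entry["uptake_percentiles_ng_per_day"]["total"]
    shares = entry["route_shares_pct"]
    top = max(shares, key=shares.get)
    print(f"{pop:5s} uptake P25/P50/P75 = {p['P25']:>8.0f} /{p['P50']:>8.0f} "
          f"/{p['P75']:>8.0f} ng/day | top route: {top} ({shares[top]:.0f}%) | "
          f"modeled {entry['modeled_median_ng_per_g_lipid']:.0f} vs "
          f"measured {entry['measured_median_ng_per_g_lipid']:.0f} ng/g lipid "
          f"(factor {entry['agreement_factor']:.2f})")
```

prints (default synthetic scenario):

```
TGP   uptake P25/P50/P75 =     7790 /   10724 /   14684 ng/day | top route: diet (99%) | modeled 1832 vs measured 1402 ng/g lipid (factor 1.31)
THEP  uptake P25/P50/P75 =    26925 /   35933 /   48711 ng/day | top route: inhalation (63%) | modeled 4860 vs measured 4198 ng/g lipid (factor 1.16)
NGP   uptake P25/P50/P75 =      717 /    1006 /    1433 ng/day | top route: diet (100%) | modeled 172 vs measured 137 ng/g lipid (factor 1.26)
NHEP  uptake P25/P50/P75 =     7731 /   11916 /   18444 ng/day | top route: diet (100%) | modeled 1971 vs measured 1550 ng/g lipid (factor 1.27)
```

Each line gives the quartiles of total daily ΣDDT uptake, the dominant
exposure route with its share of the median total, and the agreement
between the PK-modeled and the biomonitoring-measured median body
concentration. The characteristic structure — inhalation dominating only
in IRS-treated dwellings, diet everywhere else, and model-measurement
agreement well within a factor of two — emerges from the pipeline, not
from the report code.

A `ddtexpo` command-line tool exposes the same stages
(`simulate`, `fit`, `assess`, `evaluate`, `report`); try
`ddtexpo report --n-iter 2000 --seed 1`.

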