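# drmsm — progressive multi-state modelling of diabetic retinopathy

`drmsm` analyses the progression of diabetic retinopathy (DR) through
its five clinical stages — no retinopathy, mild, moderate and severe
nonproliferative DR (NPDR), and proliferative DR (PDR) — from
longitudinal clinic cohorts in which the stage is only observed at
irregular visit times.  It is aimed at ophthalmic epidemiologists and
biostatisticians who want to estimate stage-progression rates, the
effect of risk factors such as HbA1c, age, diabetes duration and
ethnicity, expected time spent in each stage, and individualized
probabilities of reaching PDR.

## Model

Disease progression is a continuous-time Markov chain on states
1–5 with an upper-triangular generator: progression is irreversible,
may skip stages between visits, and PDR is absorbing.  Covariates act
proportionally on every transition intensity with a single shared
coefficient per covariate,

```
q_rs(t) = exp( θ_rs + Σ_k β_k z_k(t) ),   1 ≤ r < s ≤ 5,
```

so `exp(β_k)` is the hazard ratio per unit of covariate k, common to
all transitions.  Time-dependent covariates (annual mean HbA1c, blood
pressure, anti-VEGF counts) are frozen at each visit's value until the
next visit, which makes every inter-visit interval a homogeneous chain:

* interval transition probabilities are products of segment matrix
  exponentials `Π exp(Q_j Δ_j)`;
* the panel likelihood multiplies the observed-entry probabilities over
  consecutive visit pairs, conditioning on the first observed state;
* the expected sojourn in state r integrates the piecewise-exponential
  survival of its exit rate in closed form per segment, truncated at a
  20-year horizon by default;
* model selection is AIC backward elimination with full refits, and
  intervals for derived probabilities come from a parametric bootstrap.

A synthetic-cohort generator (`drmsm.simulate`) reproduces the study
conditions the model targets — a 230-patient safety-net cohort with the
published stage mix, covariate distributions, declining HbA1c trend,
irregular annual visits over 2–10 years, and missingness — so every
stage of the pipeline is testable end to end without any chart data.

## Worked example

```
drmsm simulate --seed 1 --out demo
drmsm fit --input demo/cohort.csv --covariates age,dm_duration,hispanic,hba1c --out demo
drmsm report --model demo/model.json --input demo/cohort.csv --out demo
```

`fit` writes `hazard_ratios.csv`; for the seed-1 default cohort of 230
patients it prints (values rounded):

| covariate    | hazard ratio | 95% CI        | p      |
|--------------|--------------|---------------|--------|
| age          | 0.987        | (0.973–1.001) | 0.069  |
| dm_duration  | 1.000        | (0.979–1.021) | 0.989  |
| hispanic     | 1.487        | (1.085–2.039) | 0.014  |
| hba1c        | 1.117        | (1.055–1.184) | 0.0002 |

i.e. each additional percentage point of annual HbA1c raises every
stage-progression intensity by ~12% in this realization (generating
value 1.10), and Hispanic patients progress faster.  `report` adds
`sojourn_table.csv` — expected years per stage with the reduction per
+1 HbA1c point:

| stage          | sojourn (yr) | ±SD  | % reduction per +1 HbA1c |
|----------------|--------------|------|--------------------------|
| no retinopathy | 2.33         | 0.78 | 10.6                     |
| mild NPDR      | 4.17         | 1.29 | 10.2                     |
| moderate NPDR  | 5.42         | 1.53 | 9.6                      |
| severe NPDR    | 5.12         | 1.48 | 9.8                      |

plus `pdr_probability.csv` (probability of reaching PDR within 1, 4 and
7 years from each stage), `transition_rates.csv` (the time-averaged
intensity matrix for a non-Hispanic patient at mean covariates), and
`hba1c_sojourn_curve.csv` (sojourn versus HbA1c level, per stage).

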