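# wearmiss

Diagnosing the missing-data mechanism in repeated-measures wearable sleep
data: is night-level missingness **MCAR** (missing completely at random),
or is it predictable from observed variables — i.e. **consistent with MAR**
(missing at random)?

Multi-night actigraphy studies routinely lose whole nights of data — device
non-wear, battery failure, algorithm dropouts. Whether those losses are
ignorable decides which downstream analyses (imputation, likelihood-based
models, listwise deletion) are defensible. `wearmiss` implements a
sequential diagnostic pipeline for cohorts of the form *one row per
participant-night* with five sleep-stage durations (deep, light, REM,
awake, and "unmeasurable" seconds), a night index 1–5, a heart-rate-presence
indicator for the prior day, and per-participant socioeconomic covariates
(household size, education, employment, marital status, children, site):

1. **Pattern analysis** — distinct per-participant missingness patterns and
   missing/total rate tables by night, site and covariate level.
2. **Little's MCAR test** — EM maximum-likelihood estimates (μ̂, Σ̂) of a
   multivariate normal under ignorable missingness on the wide
   (stage × night + covariates) table, then the pattern-wise statistic
   d² = Σⱼ nⱼ (ȳⱼ − μ̂ₒⱼ)ᵀ Σ̂ₒⱼ⁻¹ (ȳⱼ − μ̂ₒⱼ) ~ χ²(Σⱼ pⱼ − p) under MCAR.
3. **Cluster-bootstrap random forest** — each tree is grown on a bootstrap
   resample of whole participants (never individual nights), preserving
   within-subject correlation; out-of-bag AUC above its no-signal band is
   evidence that missingness is predictable from observed variables.
4. **GEE logistic missingness model** — marginal logit model of the
   night-level missing indicator with an exchangeable working correlation,
   robust sandwich SEs, QIC comparison of working structures, and forward
   variable selection.
5. **Verdict** — the lines of evidence combine into `MCAR-not-rejected`,
   `consistent-with-MAR`, or `inconclusive`; MNAR is never asserted, since
   observed-variable models cannot rule it out.

A first-class synthetic-data generator emulates a 299-participant × 5-night
cohort with controllable MCAR/MAR/MNAR deletion; its default MAR
coefficients (intercept −1.8546, per-night slope 0.2554, employment effect
0.6671 on the logit scale) are the fitted values of the final missingness
model of the study the generator emulates, so every stage of the pipeline
is exercisable without the original (undeposited) data.

## Worked example

```python
import wearmiss as wm

ds = wm.generate(wm.GeneratorConfig(mechanism="MAR", seed=1))
print(wm.missingness_rates(ds, by="night_index").table)

little = wm.little_test(wm.to_wide(ds))
rf = wm.fit_rf(ds, n_trees=500, seed=1)
gee = wm.forward_select(ds)
print(wm.diagnose(little, rf, gee).verdict)
```

prints (seed 1):

```
  level  missing  total  fraction  percent
      1       70    299  0.234114       23
      ...
      5      121    299  0.404682       40
overall      465   1495  0.311037       31
Little's MCAR test: d2=598.35, df=495, p=0.0009634, 31 patterns
RF in-sample AUC=0.810, OOB AUC=0.563
GEE selected terms: ['night_index', 'employed', 'married']
verdict: consistent-with-MAR
```

Missingness rises from 23% on night 1 to 40% on night 5 (the generating
slope is positive), Little's test rejects MCAR, the forest's out-of-bag AUC
(0.563) sits above the no-signal band (≤ 0.55), and the GEE recovers the
night and employment effects — so the pipeline concludes the data are
consistent with MAR. The in-sample AUC (0.810) is optimistic; decisions use
the out-of-bag value.

The same pipeline is available from the shell:

```bash
wearmiss generate --mechanism MAR --seed 1 -o data.csv
wearmiss diagnose data.csv --seed 1 -o out/
```

Input CSVs are long-format (one row per participant-night), UTF-8 with a
header; column names are remappable via the `schema` argument of
`read_long_csv` or the CLI config.

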