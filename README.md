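# jaderpv

Signal detection and time-to-onset analysis for spontaneous adverse-event
report databases in the JADER schema (the Japanese Adverse Drug Event Report
database: four relational tables — `demo`, `drug`, `reac`, `hist` — keyed by
an opaque report identifier).

The package is aimed at pharmacovigilance analysts who want a tested,
scriptable version of the classic severe-cutaneous-adverse-reaction workflow:
which drugs are disproportionately reported with Stevens-Johnson syndrome /
toxic epidermal necrolysis (SJS/TEN), how the signal varies with age after
adjustment, and how quickly onsets follow the first prescription.

## What it computes

**Crude reporting odds ratio (ROR).** From the 2×2 cross-classification of
reports by suspected-drug exposure and case status (a, b, c, d),

    ROR = ad / (bc),   95% CI = exp( ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) )

with a Haldane–Anscombe 0.5 correction when a cell is empty. A *signal*
requires both the estimate and the CI lower bound to be ≥ 1.

**Adjusted ROR.** Case status is modelled by logistic regression,
`log(odds) = β₀ + β₁Y + β₂G + β₃A`, with Y the reporting year (linear), G a
female indicator and A age-stratum indicators (≤19, 20–39, 60–79, ≥80 versus
the 40–59 reference). `exp(β)` is the adjusted ROR; each term also gets a
1-df likelihood-ratio test. The same model runs inside drug-exposed subsets
(intraclass RORs). Estimation is explicit Newton–Raphson/IRLS.

**Weibull shape-parameter (WSP) test.** Days from a suspected drug's first
prescription to event onset are fitted with a two-parameter Weibull
distribution (scale α, shape β; no censoring). β < 1 with the 95% CI
excluding 1 means a decreasing hazard (early-failure pattern typical of
causal drug–event pairs); β ≈ 1 a constant background hazard; β > 1 with the
CI excluding 1 an increasing hazard.

**Synthetic databases.** `jaderpv.synthetic_data` generates JADER-schema
databases from a fully specified model (logistic case model, per-drug odds
enrichment, per-drug Weibull latencies, MCAR missingness) together with the
ground truth, so every stage is testable without the real download.

## Worked example

```python
import numpy as np
from jaderpv import (paperlike_config, generate_database,
                     build_analysis_dataset, build_contingency, crude_ror,
                     AdjustedRorModel, fit_weibull, classify_hazard)

cfg = paperlike_config(n_reports=50_000, rng_seed=42)
db, truth = generate_database(cfg)
ds = build_analysis_dataset(db)        # 50000 -> 46746 complete, 1151 cases

t = build_contingency(ds, {"allopurinol"})
r = crude_ror(t)
# 2x2 = (83, 292, 1068, 45303)
# crude ROR = 12.06 (95% CI 9.38-15.50), signal=True

model = AdjustedRorModel().fit(ds)
print(model.summary_)
#           label   beta  adjusted_ror  ci_low  ci_high  lrt_p
#  Reporting year -0.035         0.966   0.950    0.983  0.000
#   Gender female  0.092         1.097   0.975    1.233  0.123
#  Age <=19 years  0.094         1.098   0.880    1.371  0.411
# Age 20-39 years  0.528         1.695   1.420    2.024  0.000
# Age 60-79 years -0.450         0.638   0.548    0.742  0.000
#  Age >=80 years -0.372         0.689   0.554    0.857  0.001

lat = 9.44 * np.random.default_rng(0).weibull(0.64, 340)
fit = fit_weibull(lat)
# scale=11.50 (9.69-13.65), shape=0.65 (0.60-0.71) -> decreasing
print(classify_hazard(fit))
```

Reading: allopurinol's crude ROR of 12.06 (CI above 1) is a signal — exposed
reports list the event about twelve times more often, on the odds scale, than
unexposed reports. The adjusted table says reporting odds are elevated in
20–39-year-olds (adjusted ROR 1.70) and depressed in the two oldest strata,
controlling for year and sex. A fitted Weibull shape of 0.65 with CI entirely
below 1 classifies the drug's hazard as decreasing: most onsets happen soon
after the first prescription.

The same analyses run from the shell on real or simulated data:

```bash
jaderpv simulate --seed 7 --outdir simdb
jaderpv report --config run.yaml --outdir results_run
```

which writes `table1_counts.csv` (counts, reporting ratios, crude RORs),
`table2_adjusted_ror.csv`, `table3_tto.csv` (quartiles, Weibull fits, hazard
calls), per-drug onset histograms and a `manifest.json` with the row counts
at every filter step.

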