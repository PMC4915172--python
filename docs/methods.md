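# Methods

## Data model and filtering

A report database consists of four tables keyed by `report_id`: demographics
(`demo`: sex, 10-year age band, reporting year), drug records (`drug`: name,
role code, start date), reactions (`reac`: MedDRA preferred-term code, onset
date) and primary illness (`hist`, carried through but not analysed). Loading
performs no record linkage or deduplication — spontaneous reporting systems
lack a reliable case-identification key, and invented linkage would be a
stronger assumption than duplicate reports. Malformed rows (empty report id,
unrecognized role codes) are counted and logged, never silently dropped.

A report is a *case* when at least one of its reactions carries a preferred
term in the case definition (default: the three SJS/TEN terms 10042033,
10030081, 10044223; PT codes are opaque strings, no MedDRA hierarchy is
traversed). Age bands map onto five strata — ≤19, 20–39, 40–59, 60–79, ≥80 —
with decades below 20 merged downward and 80 and above merged upward, so edge
labels such as "0s" or "100s" are covered. Reports with unknown sex or age
are removed before any modelling (complete-case filter, counts logged);
reports whose year is missing or outside the configured range stay in the
dataset but are excluded from models that use the year term.

Reports, not drug records, are the counting unit everywhere: a report that
lists two suspected drugs contributes one count to each drug's 2×2 table, and
a drug-group subset counts each report once. Only *suspected*-role drug
records enter the analyses; interacting and concomitant records are retained
in the database but never counted. Reports listing only non-suspected drugs
therefore appear in denominators but in no drug's exposed cell. Drug-name
matching is exact after NFKC normalization and case-folding; brand/generic
synonym mapping is the caller's responsibility.

## Crude reporting odds ratio

For cells (a, b, c, d) the ROR is ad/(bc) with the Woolf log-normal interval
exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.959964 by default (the interval is
identical to statsmodels' `Table2x2` log-odds interval, which the tests use
as the cross-check). If any single cell is zero, 0.5 is added to all four
cells (Haldane–Anscombe) and the result flagged `corrected`; an entirely
empty margin has no defined odds ratio and is an error. The signal rule is
deliberately ≥ on both the estimate and the CI lower limit. Under the null
the 95% interval excludes 1 at close to the nominal 5% for cell sizes of
practical interest (checked by simulation in the test-suite).

## Adjusted reporting odds ratio

The adjustment model is logistic: case status on reporting year (single
linear term, coded year − base_year for conditioning), a female indicator and
four age-stratum indicators versus the 40–59 reference. Fitting is
Newton–Raphson (IRLS) with step-halving so the log-likelihood never
decreases, convergence on the score sup-norm (tol 1e-8, max 100 iterations;
a stagnation exit sits four orders of magnitude below that so the score
criterion normally governs — with a single binary covariate the fitted
exp(β) then reproduces the sample odds ratio to ~1e-10 relative). The
covariance is the inverse observed information at the optimum; CIs are Wald
on the coefficient scale, exponentiated. Diverging coefficients (|β| > 35)
are reported as perfect separation rather than returned as junk; indicator
columns with no variation (an empty stratum, a single-sex subset) are dropped
with a warning before fitting. Each non-intercept term gets a
likelihood-ratio test — refit without the column, 2·Δlog-likelihood against
χ²(1) — and "significant" means p ≤ 0.05. Subset (intraclass) analyses rerun
the identical model inside drug-exposed subsets; subsets without outcome
variation are skipped with a warning.

## Time-to-onset and the Weibull shape test

Durations are whole days from a suspected drug's *earliest* day-precision
start date to the report's earliest day-precision case-event onset.
Month/year-precision and missing dates are excluded and counted, as are
negative durations; multiple qualifying events per report collapse to the
earliest (the count of collapsed extras is reported). Quartiles use the
inclusive (n+1)-position linear-interpolation rule — for [1, 2, 3, 8, 20]
this gives Q1 1.5, Q3 14 — a purely descriptive choice. No censoring model is
used: spontaneous reports carry no at-risk time, so only observed onsets
enter.

The two-parameter Weibull fit maximizes the uncensored log-likelihood by
solving the profile score equation in the shape (the scale has a closed form
given the shape) with safeguarded Newton iteration bracketed in [1e-3, 1e3];
the profile score is strictly decreasing, so the bisection fallback makes the
solve globally convergent. Zero durations — legitimate same-day onsets — are
replaced by 0.5 day for fitting only (the log-density is undefined at zero;
the shift is configurable, and descriptive statistics keep raw zeros). CIs
are Wald on (log α, log β) from the analytic observed information,
exponentiated; profile-likelihood intervals are available via
`ci_method="profile"` as a sensitivity option. Fits with n < 10 are refused
and 10 ≤ n < 100 warns, reflecting how unstable small-sample shape estimates
are. Hazard classification requires the CI to *exclude* 1: a bound touching
1.00 stays "constant-compatible".

## Synthetic data generator

The generator emulates the study conditions, not the full richness of real
spontaneous reports. Each report draws sex (male 0.51), a 10-year age band
(distribution matching the age profile of the complete-case report counts),
and a uniform reporting year in 2004–2015. Case status follows the logistic
model above plus, for each exposed catalogue drug, a multiplicative odds
*enrichment* — association strength is injected outside the covariate model
so crude-ROR and adjusted-ROR recovery stay independently testable. The
reference `paperlike_config` uses stratum coefficients (0.284, 0.579, −0.349,
−0.327), year −0.025, female 0.104, an intercept solved by exact enumeration
so the background (unexposed) case fraction is 1.86%, five catalogue drugs at
their published exposure rates with enrichments matching their reporting
ratios, and published Weibull latencies — e.g. loxoprofen (α 9.44 d, β 0.64).
For a case report the first exposed catalogue drug defines the onset: onset =
that drug's start date + a rounded Weibull draw; all other onsets use an
exponential background latency (mean 45 d). Missingness is completely at
random, applied after generation: sex 1.5% and age 5% blanked (joint
retention ≈ 93.6%, matching the published complete-case fraction), and 5% of
start dates / 4.5% of onset dates degraded (60% blanked, 40% truncated to
month precision, emulating partial dates). Identical seeds give
byte-identical CSV output.

What the generator does **not** emulate: duplicate reports, reporter-driven
(non-random) missingness, correlated polypharmacy, within-report multiple
case events with distinct onsets, secular trends in drug usage, or real
Japanese-language headers (a column-mapping config covers the last). Passing
recovery tests therefore demonstrates correctness of the estimators under the
stated model, not robustness to those real-data features.

Two quantitative consequences worth knowing. First, the enrichment odds
ratio is *conditional* on covariates; the marginal crude ROR estimated from a
generated database is attenuated by a few percent when baseline risk varies
across strata (logistic non-collapsibility), which is visible at large n.
Second, for the same reason the whole-data adjusted stratum RORs recovered
from `paperlike_config` sit ~2–5% below exp(true β) — within the Wald CI at
the sample sizes used, and the recovery tests are phrased as CI coverage, not
point equality.

## Problem sizes and numerical choices

The test-suite runs generator-based checks at n = 20,000–200,000 reports and
the adjusted-ROR recovery at n = 50,000 × 10 replicates; the acceptance
script uses n = 800,000 for the adjusted-ROR run and 50 replicates per drug
(at the published per-drug n of 270–465) for Weibull recovery — sizes chosen
so Monte-Carlo error is small relative to the quantities being recovered
while the whole suite stays interactive. Weibull/logistic tolerances, the
z-quantile, the zero-duration shift, the minimum-n floor and the reference
stratum are all configurable parameters with the defaults given above.

Known limitations: no Firth or penalized logistic fallback for separated
subsets (they are skipped, not rescued); no PRR/IC/EBGM disproportionality
indices; no censored or covariate-adjusted Weibull regression; no MedDRA
hierarchy support. These are out of scope by design.
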