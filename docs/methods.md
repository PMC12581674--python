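# Methods

`akirank` implements the statistical machinery of a three-arm,
placebo-controlled AKI-prevention trial in critically ill adults
(calcifediol vs calcitriol vs placebo) as a reusable, tested pipeline. The
trial's patient-level data are not public, so the package pairs every
analysis component with a synthetic cohort generator calibrated to the
published summary dynamics; the analyses then run end-to-end on simulated
data with the same structure the real analysis assumes.

## The primary endpoint: hierarchical global rank

Each patient is reduced to their worst outcome within 7 days of
enrollment, ordered hierarchically:

1. **death** (worst tier),
2. **kidney replacement therapy (KRT)** among survivors,
3. **kidney injury** among event-free survivors, quantified as the
   baseline-adjusted mean percent change in serum creatinine (SCr):
   the mean of `100 * (SCr_d - SCr_0) / SCr_0` over all observations on
   days 1–7, excluding values at or after KRT start.

All patients are ranked jointly: death-tier patients share the top
(worst) midrank block, KRT-tier patients the next, and SCr-tier patients
are ordered by mean change (rank 1 = best outcome). Tied patients receive
midranks, so every ranking sums to `n(n+1)/2`. Each active arm is compared
with placebo by the Wilcoxon rank-sum test with ranks **recomputed on the
pooled two-arm set**; the primary significance threshold is two-sided
p < 0.025 per contrast (alpha split across two active arms by design).

Inference choices:

- **Exact enumeration** of all `C(n, n_a)` group assignments when the
  pooled size is ≤ 16 (configurable); the two-sided p doubles the smaller
  one-sided tail (including the observed table's point mass), capped at 1.
- **Tie-corrected normal approximation** otherwise, with variance
  `n_a n_b / 12 * ((n+1) - Σ(t³-t) / (n(n-1)))` over tie-group sizes `t`
  and a 0.5 continuity correction.
- The approximation's accuracy is inherently limited at small n because
  the rank-sum distribution is discrete: on untied 6-vs-6 data the worst
  pointwise deviation from enumeration is ≈ 0.015, and with heavy ties
  (e.g. many deaths) the discrete distribution can collapse to a few atoms
  where no smooth approximation tracks the doubled-tail p. The package
  therefore never uses the approximation below pooled n = 17; the test
  suite documents the deviation at small n rather than hiding it.
- Within-tier ordering deliberately ignores event timing (a day-2 and a
  day-6 death are tied): the hierarchy ranks *what* happened, not *when*.
- Death takes precedence over KRT when both occur.
- Event-free survivors with no usable post-baseline SCr are assigned a 0%
  change and flagged (`flag_imputed_zero` in `ranks.csv`); clinical
  endpoint data are never model-imputed.

Seven prespecified subgroup analyses (age < / ≥ 65, sex, AKI on
enrollment, ICU type, APACHE II above/below the cohort median, septic
shock, baseline 25D above/below the cohort median) recompute ranks within
each subgroup level; cells with an empty arm are reported as
not-estimable rather than raising.

## KDIGO staging and eligibility

AKI staging from labs uses closed lookback windows ending at the query
time `t` (hours from enrollment; day *d* is the bin `[24d, 24d+24)`):

- stage 1: SCr rise ≥ 0.3 mg/dL within `[t-48h, t]`, or ≥ 50% relative
  rise within `[t-7d, t]`, or urine output < 0.5 mL/kg/h for ≥ 6
  consecutive hours within the prior 24 h;
- stage 2: ≥ 100% relative SCr rise within 7 days, or oliguria ≥ 12
  consecutive hours;
- stage 3: KRT at or before `t`.

The reference creatinine is the **window minimum** and the current value
is the last observation at or before `t`. The consensus criteria do not
pin down the reference; the window minimum is the most sensitive
common operationalization and is validated in the suite against a
brute-force scan over all window pairs. Urine-output runs require
consecutive hourly observations; a gap > 1 h breaks a run (gaps are
recorded, never imputed). Whether the 12-h rule means consecutive or
cumulative hours is unspecified in the source material; consecutive-run
semantics were chosen for both rules.

Eligibility screening includes a patient iff their enrollment KDIGO stage
is ≤ 1, they have either stage-1 AKI or an AKI risk score ≥ 6 points, and
no laboratory exclusion fires (total calcium > 9.0 mg/dL, phosphate
> 6.0 mg/dL, eGFR < 15 mL/min/1.73 m²; all strict comparisons). Missing
required labs yield an `unscreenable` decision rather than a spurious
include/exclude. The risk score's published per-factor weights live in
supplementary material that is not reproduced here; the shipped weights
(`kdigo.DEFAULT_RISK_WEIGHTS`) are documented placeholders behind a
configurable `AkiRiskConfig`, with only the threshold (6 points) fixed.
eGFR is an input field, not computed (no formula is fixed by the design).

## Secondary endpoints, safety, and supporting statistics

- **Free days**: `28 - stay` for survivors to day 28, floored at 0; any
  death before day 28 scores exactly 0, handling death as a competing
  risk.
- **New or progressive AKI**: worst stage on days 1–7 exceeds the
  enrollment stage. **KRT or death**, **peak SCr**, **28-day mortality**
  are direct.
- **Safety**: hypercalcemia (> 10.7 mg/dL) and hyperphosphatemia
  (> 6.0 mg/dL) in the first 7 days; strict thresholds, peak value and
  day reported.
- **Binary contrasts**: Fisher's exact test by the point-probability
  method (sum of all hypergeometric tables with probability ≤ the
  observed table's, with a 1e-7 relative tolerance against float noise —
  the same convention as common implementations), or a 1-df chi-square
  without continuity correction. Fisher is the default; both are exposed
  since the source does not fix the choice per endpoint.
- **Longitudinal labs**: linear mixed model with random patient
  intercepts and arm, time, arm×time fixed effects; the reported p is the
  joint Wald test on the arm main-effect coefficients. A numerically zero
  arm contrast returns p = 1 (identical trajectories carry no evidence of
  separation, and the naive Wald statistic would be 0/0); singular or
  non-convergent fits return a not-estimable marker.
- **Multiple imputation**: chained equations (statsmodels' MICE engine,
  predictive mean matching) with m = 5 completed datasets by default;
  pooling is an in-package implementation of Rubin's rules
  (`T = W + (1 + 1/m) B`, classical degrees of freedom, infinite when
  B = 0). With no missing data the pooled fit equals the complete-data
  OLS exactly; with m = 1 the SE reduces to the single-imputation SE.
- **SOFA**: sum of six 0–4 organ subscores from a configurable cutoff
  grid (respiration P/F, platelets, bilirubin, MAP, GCS, creatinine);
  the cardiovascular axis accepts a direct 0–4 vasopressor-tier category.
  Missing organs score 0 and are flagged — the conservative ICU-trial
  convention; carry-forward is left to the caller.
- **Urinary KIM-1** is normalized to urinary creatinine (scale-invariant
  ratio) to control for dilution.

## Power design

The design point — 50 patients/group, a 0.62 SD standardized difference,
two-sided alpha 0.025 — gives `Phi(0.62*sqrt(50/2) - z_0.9875) = 0.805`,
reported as 80% power. The normal approximation is the default closed
form because it reproduces that printed figure; the exact noncentral-t
power (≈ 0.794 at the design point) is available behind a flag and is the
oracle the Monte-Carlo t-test power is validated against.
`required_n` inverts the closed form by stepwise search, and
`simulate_power` estimates power for the t-test, the rank-sum test
(which tracks the closed form at the 0.955 ARE-adjusted sample size on
normal shifts), and the global-rank composite with a planted SCr shift
and optional event-rate shifts.

## The synthetic cohort generator

The generator's defaults are the study conditions, not tuning knobs:

| quantity | default | basis |
| --- | --- | --- |
| arms | calcifediol / calcitriol / placebo, 1:1:1 | design |
| randomization | permuted blocks of 3, stratified by AKI on enrollment | design |
| AKI prevalence at enrollment | 35% | printed cohort description |
| 7-day death risk | 7.8 / 18.0 / 12.2 % per arm | printed event counts |
| 7-day KRT risk | 2.0 / 2.0 / 8.2 % per arm | printed event counts |
| baseline 25D | lognormal, median 16.1, IQR 10.2–25.9 ng/mL | printed distribution |
| baseline 1,25D | lognormal, median 26.9, IQR 17.5–39.1 pg/mL | printed distribution |
| 25D schedule, calcifediol | ×2.0 day 1 → ×3.0 day 5, then plateau | printed fold-changes |
| 1,25D schedule, calcitriol | ×2.5 at day 2 (satisfies "> 2-fold") | printed fold-change |
| PK noise | multiplicative lognormal, CV 15% | chosen (only medians/IQRs are printed) |
| SCr model | latent drift states improving/stable/worsening (−7/0/+6 %/day, probs 0.35/0.35/0.30), 2 %/day patient jitter, 8% daily noise | calibrated once so the mean-change distribution has median ≈ 0 and IQR ≈ (−21.5%, +18.3%) |
| event timing | uniform over days 0–7 | modeling choice (only cumulative counts are printed) |
| 28-day mortality | 16 / 30 / 24 % per arm | chosen (≈ 2× the 7-day risk; not printed per arm) |
| minerals | Ca 8.6 ± 0.45 mg/dL, PO4 3.8 ± 0.85 mg/dL patient means, arm offsets largest for calcitriol | qualitative calibration (ordering and rare hypercalcemia) |
| urine output | lognormal patient level, median 1.0 mL/kg/h | chosen; ~6% of levels fall below the 0.5 oliguria threshold |

Lognormal parameters are solved from printed medians and IQRs
(`mu = ln(median)`, `sigma = ln(q75/q25)/(2*0.6745)`). Baseline covariates
(age, sex, ICU type, APACHE II, septic shock, weight) use plausible ICU
marginals and are independent of the outcome models except through the
configured structures. All randomness flows from one root seed through
per-stage counter-based streams, so cohorts are byte-identical under a
fixed seed and each stage is independently reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: within-patient correlation between creatinine
drift and event risk (events are drawn independently of the lab
trajectories), informative missingness (the only censoring is death),
measurement batch effects, correlated covariates (e.g. APACHE II and
septic shock are independent here), or any treatment effect on clinical
outcomes beyond the configured event-rate differences. The generator
demonstrates that the analysis machinery is correct and calibrated, not
that the trial's clinical conclusions re-emerge.

## Problem sizes and numerical choices

Distributional checks in the suite use 500 patients/arm (quartile and
fold-change calibration), 2,000 draws for binomial event-rate checks, and
10,000 simulated two-arm trials for the null rejection-rate property at
alpha 0.025; Monte-Carlo tolerances are 3 binomial SEs throughout. Exact
rank-sum enumeration is exercised up to pooled n = 16; the Fisher
implementation is checked against full hypergeometric enumeration for
every 2×2 table with total n ≤ 40. Floating-point tie detection in the
rank-sum exact path uses an absolute 1e-9 guard on rank sums (midranks
are exact multiples of 0.5, so this only absorbs accumulation error).

## Known limitations

- The supplementary AKI risk-score weights and the SOFA computation
  details are not published in the main text; both ship as documented,
  configurable defaults.
- The global-rank comparison reports p-values only — no win-ratio or
  DOOR-style effect estimate — matching the trial's analysis plan.
- `longitudinal_compare` fits a random-intercept model; random slopes and
  unstructured covariance are out of scope.
- The normal-approximation rank-sum path is asymptotic; see above for its
  accuracy at small n.
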