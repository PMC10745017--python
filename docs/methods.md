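# Methods

## Scope and data model

The package validates a fixed clinical prediction rule; nothing is fitted
to data. The LUSCAB weights and the 3.5-point cutoff are taken as given
from the score's derivation study and are deliberately not re-derived.
Lung-ultrasound findings enter as pre-adjudicated booleans (no image
handling): more than three B-lines per intercostal space bilaterally in
the anterior fields, confluent B-lines bilaterally anterior, and posterior
subpleural consolidations below / at-or-above 1 cm largest diameter.
Lateral-field findings carry no score item and are ignored. A consolidation
of exactly 1 cm is assigned to the 3-point (large) item: ties go to the
higher-severity row, matching the rule-out orientation of the score.

Scores are carried internally as integer half-points, so every LUSCAB
total is an exact multiple of 0.5 and the ≥ 3.5 comparison is never
exposed to floating-point drift.

Two conventions close gaps in the printed WDF item bands: a respiratory
rate of exactly 30 breaths/min and a heart rate of exactly 120 beats/min
(both unassigned between printed bands) score 0 — gaps are closed
downward, since the measurements are integers and no rationale exists for
escalating them. A WDF total of 0 falls below the printed 1–3 mild band
and maps to mild.

Small and large posterior consolidations are separate score rows whose
mutual exclusivity is not stated anywhere; the default **additive** policy
lets both score when both are present (range 0–10.5), with an
`exclusive_max` policy (only the 3-point item counts; range 0–9.5)
available wherever a policy argument is accepted. Additive was chosen
because the two B-line rows demonstrably co-score, so rows behave as
independent items.

`support_tier` records support beyond low-flow cannula: `none`,
`lfnc_hfnc` (high-flow tier) and `ncpap_bipap_mv`. An infant on low-flow
oxygen alone has tier `none` with `oxygen_therapy` true. The four
evaluated outcomes are therefore: admission; any oxygen therapy
(`oxygen_therapy`); respiratory support excluding low-flow cannula
(tier ≠ none); and nCPAP/nBiPAP/MV (top tier). In cohorts like the one
emulated here these are nested (42% any oxygen ⊃ 36% high-flow-or-higher
⊃ 16% ventilated).

## Diagnostic accuracy

Test-positivity is score ≥ cutoff. Se/Sp/PPV/NPV are the usual 2×2 ratios;
a zero denominator yields a missing value, never 0. The empirical ROC is
enumerated at thresholds placed midway between consecutive distinct
observed scores plus ±∞ endpoints; the AUC is the Mann–Whitney probability
with ties counted ½ (computed via midranks), which equals the trapezoidal
area under that polyline exactly — both are computed and compared in the
tests. The 95% CI uses the DeLong (1988) placement-value variance with a
normal approximation, truncated to [0, 1]; DeLong was chosen as the
standard nonparametric companion of the empirical AUC (the reference
analyses were run in SPSS/STATA, whose default CI methods differ and are
not stated). The implementation is cross-checked against R's pROC
`ci.auc(..., method = "delong")` in the test suite.

`reconstruct_confusion` inverts printed summary statistics: given printed
Se, Sp and the two group sizes it rebuilds the integer 2×2 table with
counts rounded half away from zero, warning whenever no integer count can
reproduce a printed proportion to its printed resolution (taken as 0.005
on the proportion scale, half a unit in the last printed decimal of a
percent). This is how the package reproduces published predictive values
whose underlying tables were never printed.

## Survival analysis

Time to respiratory support is analysed as right-censored event-free
survival from the record's time origin (whether that origin is ED arrival
or the ultrasound examination is the data provider's choice; the package
clocks whatever the records contain). The product-limit estimator and the
two-sample Mantel–Cox log-rank statistic (χ², df 1, no continuity
correction) are computed through lifelines; ties follow the standard
events-before-censorings convention, events recorded at time 0 enter the
first risk set, and the test suite re-derives the log-rank statistic from
an independent O/E/V tabulation on random datasets to 1e-8. For the
headline 24-hour comparison the pipeline censors event-free patients at
min(follow-up, horizon) and discards events beyond the horizon as censored
at the horizon; the horizon is configurable (`--horizon-h`, default 24 h).

## Cohort statistics

Quantitative summaries are median + IQR (linear interpolation between
order statistics — numpy's default convention; at the cohort sizes in
question the difference between percentile conventions is below the
reporting resolution) or mean + SD. Group comparisons use Kruskal–Wallis
with tie correction; an all-identical pooled sample is reported as H = 0,
p = 1 by convention. Categorical comparisons use Pearson's chi-square
without continuity correction when every expected count is ≥ 5 and
Fisher's exact test otherwise (2×2 tables; larger sparse tables fall back
to chi-square with a warning). The two-sided Fisher p-value is the sum of
hypergeometric probabilities of all tables with fixed margins no more
probable than the observed one — the conventional definition, verified in
the tests against full enumeration. Spearman correlation uses average
ranks for ties with the t-approximation for p; constant inputs yield a
missing correlation with a warning. No multiple-testing adjustment is
applied anywhere.

## The synthetic cohort model

A single continuous latent severity factor drives everything; this is the
simplest structure able to reproduce the emulated cohort's marginals
jointly, and it is a modelling choice of this package, not something the
emulated study describes.

Draws occur in a fixed, documented order from one seeded generator (age →
sex → severity noise → the six WDF item noises → within-band rate draws →
the four finding draws → SaO₂ noise → outcome noise → event-time draws),
so a config + seed pair yields a byte-identical cohort CSV.

* **Age** is log-normal with μ = 0.7793, σ = 1.0092 (median 2.18 months,
  22% below 1 month, quartiles ≈ 1.1–4.3 months). Sex is Bernoulli,
  P(male) = 0.60.
* **Severity** is `z = (c·u + ε)/√(c²+1)` with `u` the standardized
  log-age, `ε ~ N(0,1)` and `c = −0.7` (younger infants run sicker);
  `z` is standard normal marginally.
* **WDF items** are ordinal cuts of `0.45·z + e_i` at per-item cutpoints
  (−0.55, 0.6, 1.8 for the four 0–3 items; 0.55 for heart rate; 2.1 for
  cyanosis), then the rate items are realised as uniform integers inside
  the selected band so records always carry raw measurements.
* **Ultrasound findings** are Bernoulli with logit `α + β·z`
  (B-lines 0 + 0.6·z; confluent −0.8 + 0.6·z; small consolidation
  −0.8 + 0.5·z; large consolidation −2.0 + 1.0·z). All intercepts are
  kept ≤ 0, which makes prevalence — and hence the cohort mean LUSCAB —
  provably non-decreasing in each slope: for α ≤ 0,
  E[logistic(α + βz)] = P(βz − L > −α) grows with the spread of the
  symmetric variate βz − L.
* **Outcomes** come from a noisy severity copy
  `o = (z + 0.65·η)/√(1 + 0.65²)`, standard normal marginally, crossed
  with ordered thresholds equal to normal quantiles of the target
  prevalences: admission Φ⁻¹(0.34), any oxygen Φ⁻¹(0.58), high-flow tier
  Φ⁻¹(0.64), ventilation tier Φ⁻¹(0.84). Large-cohort marginals (66% /
  42% / 36% / 16%) therefore match by construction, and the four outcomes
  are strictly nested.
* **Event times** for supported infants are exponential with rate
  0.1 h⁻¹, truncated at the follow-up time (default 96 h), so every
  record satisfies time ≤ follow-up. Room-air SaO₂ is
  `95.9 − 0.5·z + 2.5·N(0,1)`, clipped to [80, 100] — mean ≈ 95.7, a
  2-point gradient across support tiers, and only a weak (≈ −0.1)
  Spearman correlation with LUSCAB, mirroring the absence of a usable
  saturation signal in this population.

The free constants (WDF loading and cutpoints, finding intercepts/slopes,
outcome noise) were calibrated once with `scripts/calibrate_cohort.py` and
frozen as packaged defaults; at n = 20 000 the model reproduces median WDF
≈ 4 (IQR 3–6) with per-tier medians 4 / 5 / 6, median LUSCAB 2.5 with
per-tier medians 1.5 / 3.5 / 5.5, AUC ≈ 0.80 for the ventilation outcome
and ≈ 0.77 for high-flow-or-higher, and age-under-1-month fractions of
13% / 31% / 47% across tiers. Calibration runs at large n; a 50-infant
draw fluctuates around these values exactly as a real 50-infant cohort
would.

What the generator does **not** emulate: repeat ED visits, virus
aetiology, length of stay, admission criteria unrelated to severity
(feeding, social factors — admission is driven by the same latent factor
as support here, which overstates its coupling to severity), multi-centre
effects, and any patient-level correspondence with the original cohort.
Passing tests therefore demonstrate that the pipeline's statistics behave
correctly on data with this structure — not that the original study's
point estimates are recovered, which published marginals alone cannot
determine.

## Numerical and testing choices

Percentages are serialized on the 0–100 scale rounded half away from zero
to one decimal, only at the reporting boundary. Validation failures raise
a dedicated error type naming the offending field (and CSV row number on
ingest). Statistical property tests use seeded generators; the log-rank
type-I-error check runs 2000 two-arm null simulations (exponential event
times, n = 25 per arm, fixed administrative censoring) and expects the
α = 0.05 rejection rate within [0.035, 0.065]; generator calibration
checks run at n = 5000. These sizes keep the default suite under a minute
while leaving the Monte-Carlo standard errors well inside the asserted
tolerances.
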