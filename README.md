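# luscab

Validation tooling for the **LUSCAB score** — a bedside prognostic score for
infants (< 6 months) presenting to the emergency department with acute
bronchiolitis, combining **L**ung **U**ltra**S**ound findings, **C**linical
data and **A**ge in **B**ronchiolitis.

The package is aimed at clinical researchers who want to compute the score
on their own cohorts and run the standard validation battery: diagnostic
accuracy at the rule-out cutoff, ROC/AUC with a DeLong confidence interval,
Kaplan–Meier time-to-respiratory-support curves with a log-rank comparison,
and the usual descriptive cohort tables. Because patient-level data for the
original validation cohort were never published, a calibrated synthetic
cohort generator is included so the whole pipeline runs end to end without
any download.

## The scores

The modified **Wood–Downes–Ferres (WDF)** clinical score sums six items —
wheezing (0–3), retractions (0–3), respiratory rate (≤30 → 0, 31–45 → 1,
46–60 → 2, >60 → 3), heart rate (≤120 → 0, >120 → 1), inspiratory breath
sounds (0–3), cyanosis (0–1) — to a total of 0–14: 1–3 mild, 4–7 moderate,
8–14 severe.

The **LUSCAB** score is additive in half-point steps:

| item | points |
|---|---|
| age < 1 month | 1.5 |
| >3 B-lines per intercostal space, bilateral anterior | 1.5 |
| confluent B-lines, bilateral anterior | 1 |
| ≥1 posterior subpleural consolidation < 1 cm | 1 |
| ≥1 posterior subpleural consolidation ≥ 1 cm | 3 |
| WDF score ≥ 6 | 2.5 |

A total **≥ 3.5 points flags high risk** of escalating to nCPAP/nBiPAP or
invasive ventilation; the score's clinical value is on the rule-out side
(high negative predictive value below the cutoff). For a 2×2 table at the
cutoff the pipeline reports Se = TP/(TP+FN), Sp = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN); the AUC is the Mann–Whitney pairwise
probability (ties ½) with a DeLong 95% interval.

## Worked example

Scoring one infant in Python:

```python
>>> from luscab import WDFItems, LUSFindings, score_record
>>> score_record(
...     age_months=0.8,
...     wdf=WDFItems(wheezing=2, retractions=1, respiratory_rate=52,
...                  heart_rate=138, inspiratory_breath_sounds=1, cyanosis=False),
...     lus=LUSFindings(blines_gt3_bilateral_anterior=True,
...                     posterior_consolidation_small=True),
... )
ScoreResult(wdf_total=7, wdf_band='moderate', luscab_total=6.5, high_risk=True)
```

The WDF items sum to 7 (moderate); LUSCAB collects 1.5 (age < 1 month)
+ 1.5 (B-lines) + 1 (small consolidation) + 2.5 (WDF ≥ 6) = 6.5 ≥ 3.5,
so the infant is flagged high risk.

The full synthetic demo, from the command line:

```sh
luscab run-all --simulate --n 50 --seed 1 --report report.json
```

simulates a 50-infant cohort from the calibrated latent-severity model,
scores it, and writes the complete validation report. With seed 1 the
cohort has 34 admissions, 11 infants on high-flow-or-higher support and 4
reaching nCPAP/nBiPAP/MV; the nCPAP/nBiPAP/MV entry of
`accuracy_by_outcome` reads

```json
{"confusion": {"tp": 4, "fp": 10, "tn": 36, "fn": 0},
 "sensitivity_pct": 100.0, "specificity_pct": 78.3,
 "ppv_pct": 28.6, "npv_pct": 100.0,
 "auc": 0.878, "auc_ci_low": 0.768, "auc_ci_high": 0.987}
```

— every infant who went on to ventilatory support scored ≥ 3.5 (NPV 100%,
low PPV: the score rules out, it does not rule in), with AUC 0.88
(95% CI 0.77–0.99). The survival section compares the two cutoff groups
over the first 24 h: event-free survival 78.6% vs 100% for the
nCPAP/nBiPAP/MV outcome, log-rank χ² = 8.32, p = 0.004. Other subcommands
(`score`, `describe`, `validate`, `survival`, `simulate`) expose the
individual stages; the report layout is documented in
`docs/report_schema.md` and the model in `docs/methods.md`.

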