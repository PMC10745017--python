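# Validation report schema

`luscab run-all` (and `run_validation` in Python) emits one JSON object.
All percentages are on the 0–100 scale, rounded half away from zero to one
decimal; proportions (AUC, survival) are on [0, 1]. Undefined quantities
are `null`, never 0.

```text
{
  "provenance": {
    "package": "luscab", "version": str,
    "n": int, "cutoff": float, "horizon_h": float,
    "consolidation_policy": "additive" | "exclusive_max",
    // plus either {"input": path} or {"simulated": true, "seed": int, "config": {...}}
  },

  "cohort_summary": {
    "n": int,
    "age_months":  {"n", "median", "q1", "q3"},
    "age_lt_1mo":  {"n": int, "pct": float},
    "male":        {"n": int, "pct": float},
    "sao2_room_air": {"n", "mean", "sd"},
    "wdf_total":   {"n", "median", "q1", "q3"},
    "luscab_total":{"n", "median", "q1", "q3"},
    "outcomes":    {outcome: {"n": int, "pct": float}},
    "sao2_luscab_spearman": {"rho": float|null, "p_value": float|null}
  },

  "group_comparisons": [            // by support tier
    {"variable": str,
     "test": "kruskal_wallis" | "chi_square" | "fisher_exact",
     "statistic": float, "p_value": float,
     "groups": {tier: summary-or-counts}}
  ],

  "accuracy_by_outcome": {          // admission, oxygen, support, ncpap_mv
    outcome: {
      "evaluable": bool,            // false => only "reason" + group sizes
      "confusion": {"tp", "fp", "tn", "fn"},
      "n_positive": int, "n_negative": int,
      "sensitivity_pct": float|null, "specificity_pct": float|null,
      "ppv_pct": float|null, "npv_pct": float|null,
      "auc": float, "auc_ci_low": float, "auc_ci_high": float   // DeLong 95%
    }
  },

  "survival": {                     // support, ncpap_mv
    outcome: {
      "evaluable": bool,
      "horizon_h": float,
      "groups": {
        "high_risk" | "low_risk": {
          "n": int,
          "event_times_h": [float], "survival": [float],
          "at_risk": [int], "n_events": [int],
          "event_free_at_horizon_pct": float
        }
      },
      "logrank": {"chi_square": float, "df": 1, "p_value": float} | null
    }
  }
}
```

Outcome keys: `admission` (hospital admission), `oxygen` (any oxygen
therapy including low-flow cannula), `support` (high-flow cannula or
higher), `ncpap_mv` (nCPAP/nBiPAP/invasive ventilation). An outcome with
no positives or no negatives in the cohort is reported with
`"evaluable": false` rather than failing the run; a survival entry whose
horizon window contains no events keeps the per-group curves but reports
`"logrank": null`.
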