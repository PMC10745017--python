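"""End-to-end validation report: descriptive tables, accuracy, survival.

``run_validation`` takes a cohort of patient records and produces the
machine-readable analogue of a score-validation paper's results section:

* ``cohort_summary`` — whole-cohort descriptives (ages, scores, outcome
  counts, SaO2, and the SaO2-vs-LUSCAB Spearman correlation);
* ``group_comparisons`` — per-support-tier summaries with Kruskal-Wallis /
  chi-square / Fisher tests;
* ``accuracy_by_outcome`` — for each of the four outcomes (admission, any
  oxygen therapy, high-flow-or-higher respiratory support, nCPAP/nBiPAP/MV):
  the 2x2 table at the cutoff, Se/Sp/PPV/NPV, and ROC AUC with DeLong CI;
* ``survival`` — Kaplan-Meier event-free curves by cutoff group with the
  log-rank comparison, for the two support outcomes, right-censored at the
  horizon (default 24 h from the record's time origin).

Percentages are serialized on the 0-100 scale rounded half away from zero
to one decimal; internal computation keeps full precision.
"""

from __future__ import annotations

import json
import math
from typing import Sequence

import numpy as np

from . import accuracy as acc
from . import cohort_stats as cs
from . import survival as surv
from .records import PatientRecord, cohort_to_frame
from .scoring import LUSCAB_CUTOFF, ValidationError, score_frame

__all__ = [
    "OUTCOMES",
    "outcome_vector",
    "run_validation",
    "write_report",
    "check_report_schema",
]

#: Outcome name -> predicate over a PatientRecord.  ``support`` is
#: high-flow-or-higher (excluding low-flow cannula); ``oxygen`` is any
#: oxygen therapy including low-flow.
OUTCOMES = {
    "admission": lambda r: r.admitted,
    "oxygen": lambda r: r.oxygen_therapy,
    "support": lambda r: r.support_tier != "none",
    "ncpap_mv": lambda r: r.support_tier == "ncpap_bipap_mv",
}

_SURVIVAL_OUTCOMES = ("support", "ncpap_mv")


def outcome_vector(cohort: Sequence[PatientRecord], outcome: str) -> np.ndarray:
    """Boolean outcome indicator for each record."""
    try:
        pred = OUTCOMES[outcome]
    except KeyError:
        raise ValidationError(f"unknown outcome {outcome!r}; choose from {list(OUTCOMES)}")
    return np.array([pred(r) for r in cohort], dtype=bool)


def _pct(x: float | None) -> float | None:
    """Percent on the 0-100 scale, one decimal, rounding half away from zero."""
    if x is None:
        return None
    v = x * 1000.0
    return (math.floor(v + 0.5) if v >= 0 else -math.floor(-v + 0.5)) / 10.0


def _round(x: float | None, d: int = 3) -> float | None:
    return None if x is None else round(float(x), d)


def _summary_dict(s: cs.Summary) -> dict:
    out = {"n": s.n}
    for k in ("median", "q1", "q3", "mean", "sd"):
        v = getattr(s, k)
        if v is not None:
            out[k] = _round(v)
    return out


def _accuracy_entry(scores: np.ndarray, y: np.ndarray, cutoff: float) -> dict:
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return {
            "evaluable": False,
            "reason": f"outcome has {n_pos} positives and {n_neg} negatives",
            "n_positive": n_pos,
            "n_negative": n_neg,
        }
    cm = acc.confusion_at_cutoff(scores, y, cutoff)
    st = acc.diagnostic_stats(cm)
    roc = acc.roc_auc(scores, y)
    return {
        "evaluable": True,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "n_positive": cm.n_positive,
        "n_negative": cm.n_negative,
        "sensitivity_pct": _pct(st.sensitivity),
        "specificity_pct": _pct(st.specificity),
        "ppv_pct": _pct(st.ppv),
        "npv_pct": _pct(st.npv),
        "auc": _round(roc.auc),
        "auc_ci_low": _round(roc.auc_ci_low),
        "auc_ci_high": _round(roc.auc_ci_high),
    }


def _time_to_event(
    cohort: Sequence[PatientRecord], outcome: str, horizon_h: float
) -> list[surv.TimeToEvent]:
    y = outcome_vector(cohort, outcome)
    out = []
    for r, is_event in zip(cohort, y):
        censor_at = min(r.followup_h, horizon_h)
        if is_event and r.time_to_support_h is not None and r.time_to_support_h <= horizon_h:
            out.append(surv.TimeToEvent(time_h=r.time_to_support_h, event=True))
        else:
            out.append(surv.TimeToEvent(time_h=censor_at, event=False))
    return out


def _km_dict(est: surv.KMEstimate, horizon_h: float) -> dict:
    return {
        "n": est.n,
        "event_times_h": [float(t) for t in est.event_times],
        "survival": [_round(s, 4) for s in est.survival],
        "at_risk": [int(v) for v in est.at_risk],
        "n_events": [int(v) for v in est.n_events],
        "event_free_at_horizon_pct": _pct(surv.km_survival_at(est, horizon_h)),
    }


def _survival_entry(
    cohort: Sequence[PatientRecord], high_risk: np.ndarray, outcome: str, horizon_h: float
) -> dict:
    tte = _time_to_event(cohort, outcome, horizon_h)
    grp_hi = [t for t, h in zip(tte, high_risk) if h]
    grp_lo = [t for t, h in zip(tte, high_risk) if not h]
    if not grp_hi or not grp_lo:
        return {"evaluable": False, "reason": "one cutoff group is empty"}
    n_events = sum(t.event for t in tte)
    entry = {
        "evaluable": True,
        "horizon_h": horizon_h,
        "groups": {
            "high_risk": _km_dict(surv.km_fit(grp_hi), horizon_h),
            "low_risk": _km_dict(surv.km_fit(grp_lo), horizon_h),
        },
    }
    if n_events == 0:
        entry["logrank"] = None
        entry["reason"] = "no events within the horizon; log-rank undefined"
    else:
        lr = surv.logrank_test(grp_hi, grp_lo)
        entry["logrank"] = {
            "chi_square": _round(lr.chi_square, 4),
            "df": lr.df,
            "p_value": _round(lr.p_value, 4),
        }
    return entry


def _cohort_summary(cohort, frame) -> dict:
    ages = frame["age_months"].to_numpy(dtype=float)
    luscab = frame["luscab_total"].to_numpy(dtype=float)
    sao2 = frame["sao2_room_air"].to_numpy(dtype=float)
    n = len(cohort)
    counts = {name: int(outcome_vector(cohort, name).sum()) for name in OUTCOMES}
    rho, p = cs.spearman_correlation(sao2, luscab) if n >= 3 and np.ptp(sao2) > 0 and np.ptp(luscab) > 0 else (None, None)
    return {
        "n": n,
        "age_months": _summary_dict(cs.summarize(ages)),
        "age_lt_1mo": {"n": int((ages < 1).sum()), "pct": _pct(float((ages < 1).mean()))},
        "male": {
            "n": int((frame["sex"] == "male").sum()),
            "pct": _pct(float((frame["sex"] == "male").mean())),
        },
        "sao2_room_air": _summary_dict(cs.summarize(sao2, kind="mean_sd")),
        "wdf_total": _summary_dict(cs.summarize(frame["wdf_total"].to_numpy(dtype=float))),
        "luscab_total": _summary_dict(cs.summarize(luscab)),
        "outcomes": {
            name: {"n": counts[name], "pct": _pct(counts[name] / n)} for name in counts
        },
        "sao2_luscab_spearman": {"rho": _round(rho), "p_value": _round(p)},
    }


def _group_comparisons(frame) -> list[dict]:
    tiers = ["none", "lfnc_hfnc", "ncpap_bipap_mv"]
    present = [t for t in tiers if (frame["support_tier"] == t).any()]
    out = []
    if len(present) < 2:
        return out
    by_tier = {t: frame[frame["support_tier"] == t] for t in present}
    for var in ("age_months", "sao2_room_air", "wdf_total", "luscab_total"):
        comp = cs.compare_groups({t: g[var].to_numpy(dtype=float) for t, g in by_tier.items()}, var)
        out.append(
            {
                "variable": var,
                "test": comp.test_name,
                "statistic": _round(comp.statistic, 4),
                "p_value": _round(comp.p_value, 4),
                "groups": {g: _summary_dict(s) for g, s in comp.summaries.items()},
            }
        )
    for var, indicator in (
        ("sex_male", frame["sex"] == "male"),
        ("age_lt_1mo", frame["age_months"] < 1),
    ):
        table = np.array(
            [
                [int(indicator[frame["support_tier"] == t].sum()) for t in present],
                [int((~indicator)[frame["support_tier"] == t].sum()) for t in present],
            ]
        )
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            continue  # degenerate margins: no testable contrast
        comp = cs.compare_categorical(table, var, group_labels=present)
        out.append(
            {
                "variable": var,
                "test": comp.test_name,
                "statistic": _round(comp.statistic, 4),
                "p_value": _round(comp.p_value, 4),
                "groups": {
                    t: {"n": int(indicator[frame["support_tier"] == t].sum()),
                        "total": int((frame["support_tier"] == t).sum())}
                    for t in present
                },
            }
        )
    return out


def run_validation(
    cohort: Sequence[PatientRecord],
    cutoff: float = LUSCAB_CUTOFF,
    horizon_h: float = 24.0,
    consolidation_policy: str = "additive",
    provenance: dict | None = None,
) -> dict:
    """Score a cohort and assemble the full validation report."""
    cohort = list(cohort)
    if not cohort:
        raise ValidationError("cohort is empty")
    frame = score_frame(cohort_to_frame(cohort), consolidation_policy)
    scores = frame["luscab_total"].to_numpy(dtype=float)
    high_risk = scores >= cutoff

    from . import __version__

    report: dict = {
        "provenance": {
            "package": "luscab",
            "version": __version__,
            "n": len(cohort),
            "cutoff": cutoff,
            "horizon_h": horizon_h,
            "consolidation_policy": consolidation_policy,
            **(provenance or {}),
        },
        "cohort_summary": _cohort_summary(cohort, frame),
        "group_comparisons": _group_comparisons(frame),
        "accuracy_by_outcome": {
            name: _accuracy_entry(scores, outcome_vector(cohort, name), cutoff)
            for name in OUTCOMES
        },
        "survival": {
            name: _survival_entry(cohort, high_risk, name, horizon_h)
            for name in _SURVIVAL_OUTCOMES
        },
    }
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def check_report_schema(report: dict) -> list[str]:
    """Structural check of a validation report; returns a list of problems.

    The full schema is documented in docs/report_schema.md.
    """
    problems = []
    for key in ("provenance", "cohort_summary", "group_comparisons",
                "accuracy_by_outcome", "survival"):
        if key not in report:
            problems.append(f"missing top-level key {key!r}")
    if problems:
        return problems
    prov = report["provenance"]
    for key in ("package", "version", "n", "cutoff", "horizon_h"):
        if key not in prov:
            problems.append(f"provenance missing {key!r}")
    for name in OUTCOMES:
        entry = report["accuracy_by_outcome"].get(name)
        if entry is None:
            problems.append(f"accuracy_by_outcome missing {name!r}")
            continue
        if entry.get("evaluable"):
            cm = entry.get("confusion", {})
            if sorted(cm) != ["fn", "fp", "tn", "tp"]:
                problems.append(f"{name}: malformed confusion matrix")
            for k in ("sensitivity_pct", "specificity_pct", "ppv_pct", "npv_pct"):
                v = entry.get(k)
                if v is not None and not 0 <= v <= 100:
                    problems.append(f"{name}: {k} outside [0, 100]")
            if not (entry.get("auc_ci_low") <= entry.get("auc") <= entry.get("auc_ci_high")):
                problems.append(f"{name}: AUC outside its own CI")
    for name in _SURVIVAL_OUTCOMES:
        if name not in report["survival"]:
            problems.append(f"survival missing {name!r}")
    return problems
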