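"""Clinical severity scores: modified Wood-Downes-Ferres (WDF) and LUSCAB.

The WDF score grades bronchiolitis severity from six bedside items
(wheezing, retractions, respiratory rate, heart rate, inspiratory breath
sounds, cyanosis) on a 0-14 scale: 0-3 mild, 4-7 moderate, 8-14 severe.

The LUSCAB score combines lung-ultrasound findings with the WDF score and
age into a half-point additive scale (0-10.5):

    age < 1 month                                   1.5
    >3 B-lines per intercostal space, bilateral
        anterior                                    1.5
    confluent B-lines, bilateral anterior           1.0
    posterior subpleural consolidation < 1 cm       1.0
    posterior subpleural consolidation >= 1 cm      3.0
    WDF total >= 6                                  2.5

A total of 3.5 points or more flags the infant as high risk for escalating
to nCPAP/nBiPAP/invasive ventilation; below 3.5 is the rule-out side.

Points are carried internally as integer half-points so every returned
total is an exact multiple of 0.5 with no floating-point drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

__all__ = [
    "WDFItems",
    "LUSFindings",
    "ScoreResult",
    "wdf_score",
    "wdf_band",
    "luscab_score",
    "classify_high_risk",
    "score_record",
    "score_frame",
    "LuscabScorer",
    "HighRiskClassifier",
    "LUSCAB_CUTOFF",
    "ConsolidationPolicy",
]

#: High-risk cutoff in LUSCAB points (score >= cutoff is test-positive).
LUSCAB_CUTOFF = 3.5

#: Cutoff in internal half-point units.
_CUTOFF_HALF = 7

ConsolidationPolicy = Literal["additive", "exclusive_max"]

# LUSCAB item weights in half-point units.
_HP_AGE_LT_1MO = 3  # 1.5 points
_HP_BLINES_GT3 = 3  # 1.5 points
_HP_CONFLUENT = 2  # 1 point
_HP_CONSOL_SMALL = 2  # 1 point
_HP_CONSOL_LARGE = 6  # 3 points
_HP_WDF_GE6 = 5  # 2.5 points


class ValidationError(ValueError):
    """Raised when an input violates a documented domain invariant."""


def _check_ordinal(name: str, value: int, high: int) -> int:
    if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
        raise ValidationError(f"{name} must be an integer, got {value!r}")
    if not 0 <= value <= high:
        raise ValidationError(f"{name} must be in [0, {high}], got {value}")
    return int(value)


@dataclass(frozen=True)
class WDFItems:
    """Raw findings behind the six modified Wood-Downes-Ferres items.

    Respiratory and heart rate are stored as the raw measurements
    (breaths/min, beats/min); their point contributions are computed from
    the banding at scoring time, never stored.
    """

    wheezing: int  # 0 none, 1 end-expiratory, 2 entire expiration, 3 in+expiration
    retractions: int  # 0-3 escalating recruitment of accessory muscles
    respiratory_rate: int  # breaths/min
    heart_rate: int  # beats/min
    inspiratory_breath_sounds: int  # 0 normal ... 3 silent thorax
    cyanosis: bool

    def __post_init__(self) -> None:
        _check_ordinal("wheezing", self.wheezing, 3)
        _check_ordinal("retractions", self.retractions, 3)
        _check_ordinal("inspiratory_breath_sounds", self.inspiratory_breath_sounds, 3)
        if not isinstance(self.respiratory_rate, (int, np.integer)) or self.respiratory_rate < 0:
            raise ValidationError(
                f"respiratory_rate must be a non-negative integer, got {self.respiratory_rate!r}"
            )
        if not isinstance(self.heart_rate, (int, np.integer)) or self.heart_rate < 0:
            raise ValidationError(
                f"heart_rate must be a non-negative integer, got {self.heart_rate!r}"
            )
        if not isinstance(self.cyanosis, (bool, np.bool_)):
            raise ValidationError(f"cyanosis must be boolean, got {self.cyanosis!r}")


@dataclass(frozen=True)
class LUSFindings:
    """Presence/absence of the four scoreable lung-ultrasound findings.

    The four flags are independent booleans; in particular an infant may
    show both a small (<1 cm) and a large (>=1 cm) posterior subpleural
    consolidation at once.
    """

    blines_gt3_bilateral_anterior: bool = False
    confluent_blines_bilateral_anterior: bool = False
    posterior_consolidation_small: bool = False  # largest diameter < 1 cm
    posterior_consolidation_large: bool = False  # largest diameter >= 1 cm

    def __post_init__(self) -> None:
        for name in (
            "blines_gt3_bilateral_anterior",
            "confluent_blines_bilateral_anterior",
            "posterior_consolidation_small",
            "posterior_consolidation_large",
        ):
            v = getattr(self, name)
            if not isinstance(v, (bool, np.bool_)):
                raise ValidationError(f"{name} must be boolean, got {v!r}")


@dataclass(frozen=True)
class ScoreResult:
    """Scores computed for one infant."""

    wdf_total: int
    wdf_band: str
    luscab_total: float
    high_risk: bool


def _respiratory_rate_points(rate: int) -> int:
    # Band boundaries close the unassigned value 30 downward: <=30 scores 0.
    if rate <= 30:
        return 0
    if rate <= 45:
        return 1
    if rate <= 60:
        return 2
    return 3


def _heart_rate_points(rate: int) -> int:
    # The unassigned value 120 is closed downward: <=120 scores 0.
    return 0 if rate <= 120 else 1


def wdf_score(items: WDFItems) -> int:
    """Total modified Wood-Downes-Ferres score, an integer in [0, 14].

    Sum of the six item points; respiratory and heart rate are banded
    (RR: <=30 -> 0, 31-45 -> 1, 46-60 -> 2, >60 -> 3; HR: <=120 -> 0,
    >120 -> 1).
    """
    total = (
        items.wheezing
        + items.retractions
        + _respiratory_rate_points(items.respiratory_rate)
        + _heart_rate_points(items.heart_rate)
        + items.inspiratory_breath_sounds
        + int(items.cyanosis)
    )
    return int(total)


def wdf_band(total: int) -> str:
    """Severity band for a WDF total: mild (0-3), moderate (4-7), severe (8-14).

    A total of 0 falls below the printed 1-3 mild band and is mapped to
    mild, there being no lower category.
    """
    if not isinstance(total, (int, np.integer)) or isinstance(total, bool):
        raise ValidationError(f"WDF total must be an integer, got {total!r}")
    if not 0 <= total <= 14:
        raise ValidationError(f"WDF total must be in [0, 14], got {total}")
    if total <= 3:
        return "mild"
    if total <= 7:
        return "moderate"
    return "severe"


def _luscab_half_points(
    age_months: float,
    wdf_total: int,
    lus: LUSFindings,
    consolidation_policy: ConsolidationPolicy,
) -> int:
    if age_months < 0:
        raise ValidationError(f"age_months must be non-negative, got {age_months}")
    if not 0 <= int(wdf_total) <= 14:
        raise ValidationError(f"wdf_total must be in [0, 14], got {wdf_total}")
    if consolidation_policy not in ("additive", "exclusive_max"):
        raise ValidationError(
            f"consolidation_policy must be 'additive' or 'exclusive_max', got {consolidation_policy!r}"
        )
    hp = 0
    if age_months < 1.0:
        hp += _HP_AGE_LT_1MO
    if lus.blines_gt3_bilateral_anterior:
        hp += _HP_BLINES_GT3
    if lus.confluent_blines_bilateral_anterior:
        hp += _HP_CONFLUENT
    small, large = lus.posterior_consolidation_small, lus.posterior_consolidation_large
    if consolidation_policy == "exclusive_max" and small and large:
        hp += _HP_CONSOL_LARGE
    else:
        if small:
            hp += _HP_CONSOL_SMALL
        if large:
            hp += _HP_CONSOL_LARGE
    if wdf_total >= 6:
        hp += _HP_WDF_GE6
    return hp


def luscab_score(
    age_months: float,
    wdf_total: int,
    lus: LUSFindings,
    consolidation_policy: ConsolidationPolicy = "additive",
) -> float:
    """LUSCAB total in points (an exact multiple of 0.5).

    Under the default ``additive`` policy every satisfied item scores, so
    the range is [0, 10.5].  Under ``exclusive_max`` a chest showing both a
    small and a large posterior consolidation scores only the 3-point large
    item (range [0, 9.5]).  A consolidation of exactly 1 cm belongs to the
    large item: ties go to the higher-severity row, consistent with the
    score's rule-out orientation.
    """
    return _luscab_half_points(age_months, wdf_total, lus, consolidation_policy) / 2.0


def classify_high_risk(luscab_total: float) -> bool:
    """True iff the LUSCAB total reaches the 3.5-point high-risk cutoff."""
    if luscab_total < 0:
        raise ValidationError(f"luscab_total must be non-negative, got {luscab_total}")
    return bool(luscab_total >= LUSCAB_CUTOFF)


def score_record(
    age_months: float,
    wdf: WDFItems | None = None,
    wdf_total: int | None = None,
    lus: LUSFindings | None = None,
    consolidation_policy: ConsolidationPolicy = "additive",
) -> ScoreResult:
    """Score one infant from raw WDF items (or a precomputed total) and LUS findings.

    When both ``wdf`` items and a precomputed ``wdf_total`` are supplied
    they must agree; an inconsistency is a validation error, never silently
    resolved in favour of one source.
    """
    if wdf is None and wdf_total is None:
        raise ValidationError("either wdf items or wdf_total must be supplied")
    if wdf is not None:
        computed = wdf_score(wdf)
        if wdf_total is not None and int(wdf_total) != computed:
            raise ValidationError(
                f"precomputed wdf_total={wdf_total} disagrees with items (sum {computed})"
            )
        total = computed
    else:
        if not isinstance(wdf_total, (int, np.integer)) or not 0 <= wdf_total <= 14:
            raise ValidationError(f"wdf_total must be an integer in [0, 14], got {wdf_total!r}")
        total = int(wdf_total)
    if lus is None:
        lus = LUSFindings()
    ltotal = luscab_score(age_months, total, lus, consolidation_policy)
    return ScoreResult(
        wdf_total=total,
        wdf_band=wdf_band(total),
        luscab_total=ltotal,
        high_risk=classify_high_risk(ltotal),
    )


# ---------------------------------------------------------------------------
# DataFrame-level scoring

_LUS_COLUMNS = {
    "blines_gt3_bilat_ant": "blines_gt3_bilateral_anterior",
    "confluent_blines_bilat_ant": "confluent_blines_bilateral_anterior",
    "post_consol_small": "posterior_consolidation_small",
    "post_consol_large": "posterior_consolidation_large",
}

_WDF_ITEM_COLUMNS = ("wdf_wheezing", "wdf_retractions", "resp_rate", "heart_rate",
                     "wdf_breath_sounds", "wdf_cyanosis")


def _row_items(row: pd.Series) -> WDFItems:
    return WDFItems(
        wheezing=int(row["wdf_wheezing"]),
        retractions=int(row["wdf_retractions"]),
        respiratory_rate=int(row["resp_rate"]),
        heart_rate=int(row["heart_rate"]),
        inspiratory_breath_sounds=int(row["wdf_breath_sounds"]),
        cyanosis=bool(int(row["wdf_cyanosis"])),
    )


def _row_lus(row: pd.Series) -> LUSFindings:
    return LUSFindings(**{attr: bool(int(row[col])) for col, attr in _LUS_COLUMNS.items()})


def score_frame(
    frame: pd.DataFrame, consolidation_policy: ConsolidationPolicy = "additive"
) -> pd.DataFrame:
    """Append wdf_total, wdf_band, luscab_total and high_risk columns.

    ``frame`` follows the cohort CSV schema: either the raw WDF item
    columns (wdf_wheezing, wdf_retractions, resp_rate, heart_rate,
    wdf_breath_sounds, wdf_cyanosis) or a precomputed ``wdf_total`` column,
    plus the four 0/1 lung-ultrasound columns and ``age_months``.
    """
    has_items = all(c in frame.columns for c in _WDF_ITEM_COLUMNS)
    has_total = "wdf_total" in frame.columns
    if not has_items and not has_total:
        raise ValidationError(
            "cohort frame needs either the six WDF item columns or a wdf_total column"
        )
    missing = [c for c in _LUS_COLUMNS if c not in frame.columns]
    if missing or "age_months" not in frame.columns:
        raise ValidationError(f"cohort frame is missing columns: {missing + (['age_months'] if 'age_months' not in frame.columns else [])}")

    out = frame.copy()
    results = []
    for idx, row in frame.iterrows():
        try:
            res = score_record(
                age_months=float(row["age_months"]),
                wdf=_row_items(row) if has_items else None,
                wdf_total=int(row["wdf_total"]) if has_total and pd.notna(row.get("wdf_total")) else None,
                lus=_row_lus(row),
                consolidation_policy=consolidation_policy,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
        results.append(res)
    out["wdf_total"] = [r.wdf_total for r in results]
    out["wdf_band"] = [r.wdf_band for r in results]
    out["luscab_total"] = [r.luscab_total for r in results]
    out["high_risk"] = [r.high_risk for r in results]
    return out


class LuscabScorer(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer computing WDF and LUSCAB scores.

    Operates on cohort DataFrames in the documented CSV schema and appends
    ``wdf_total``, ``wdf_band``, ``luscab_total`` and ``high_risk`` columns,
    so scoring composes with sklearn pipelines and model selection.

    Parameters
    ----------
    consolidation_policy : {"additive", "exclusive_max"}
        Whether small and large posterior consolidations both score when
        both are present (additive, default) or only the large item does.
    """

    def __init__(self, consolidation_policy: ConsolidationPolicy = "additive"):
        self.consolidation_policy = consolidation_policy

    def fit(self, X: pd.DataFrame, y=None) -> "LuscabScorer":
        if self.consolidation_policy not in ("additive", "exclusive_max"):
            raise ValidationError(
                f"consolidation_policy must be 'additive' or 'exclusive_max',"
                f" got {self.consolidation_policy!r}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return score_frame(X, self.consolidation_policy)


class HighRiskClassifier(BaseEstimator, ClassifierMixin):
    """Fixed-rule classifier: LUSCAB total >= cutoff flags high risk.

    The cutoff (default 3.5 points) is taken as given from the score's
    derivation study; ``fit`` only validates and records classes.  The
    decision function is the LUSCAB total itself, which is what ROC
    analysis thresholds over.
    """

    def __init__(
        self,
        cutoff: float = LUSCAB_CUTOFF,
        consolidation_policy: ConsolidationPolicy = "additive",
    ):
        self.cutoff = cutoff
        self.consolidation_policy = consolidation_policy

    def fit(self, X: pd.DataFrame, y=None) -> "HighRiskClassifier":
        if self.cutoff < 0:
            raise ValidationError(f"cutoff must be non-negative, got {self.cutoff}")
        self.classes_ = np.array([False, True])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        scored = X if "luscab_total" in X.columns else score_frame(X, self.consolidation_policy)
        return scored["luscab_total"].to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.decision_function(X) >= self.cutoff
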