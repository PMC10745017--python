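"""Patient-level records and the cohort CSV schema.

One row per infant: demographics, the six raw Wood-Downes-Ferres items (or
a precomputed total), the four adjudicated lung-ultrasound flags, and the
outcomes — hospital admission, any oxygen therapy (low-flow cannula or
higher), the respiratory-support tier, and hours from the time origin to
support initiation.

The ``support_tier`` field records support beyond low-flow cannula:
``none`` (possibly still on low-flow oxygen, captured by the separate
``oxygen_therapy`` flag), ``lfnc_hfnc`` (high-flow cannula tier), and
``ncpap_bipap_mv`` (non-invasive or invasive ventilation, the score's
rule-out target).  A tier other than ``none`` implies the oxygen flag and
a recorded time to support, never later than the follow-up time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .scoring import LUSFindings, ValidationError, WDFItems, wdf_score

logger = logging.getLogger("luscab")

__all__ = [
    "PatientRecord",
    "SUPPORT_TIERS",
    "CSV_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_to_frame",
    "frame_to_cohort",
]

SUPPORT_TIERS = ("none", "lfnc_hfnc", "ncpap_bipap_mv")

#: Canonical column order of the cohort CSV (item-level schema).
CSV_COLUMNS = [
    "patient_id",
    "age_months",
    "sex",
    "sao2_room_air",
    "wdf_wheezing",
    "wdf_retractions",
    "resp_rate",
    "heart_rate",
    "wdf_breath_sounds",
    "wdf_cyanosis",
    "blines_gt3_bilat_ant",
    "confluent_blines_bilat_ant",
    "post_consol_small",
    "post_consol_large",
    "admitted",
    "oxygen_therapy",
    "support_tier",
    "time_to_support_h",
    "followup_h",
]

_MANDATORY = [c for c in CSV_COLUMNS if not c.startswith(("wdf_", "resp_rate", "heart_rate"))]


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age_months: float
    sex: str
    sao2_room_air: float
    lus: LUSFindings
    admitted: bool
    oxygen_therapy: bool
    support_tier: str
    followup_h: float
    time_to_support_h: float | None = None
    wdf: WDFItems | None = None
    wdf_total: int | None = None

    def __post_init__(self) -> None:
        if self.age_months < 0:
            raise ValidationError(f"age_months must be >= 0, got {self.age_months}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 0 <= self.sao2_room_air <= 100:
            raise ValidationError(f"sao2_room_air must be in [0, 100], got {self.sao2_room_air}")
        if self.support_tier not in SUPPORT_TIERS:
            raise ValidationError(
                f"support_tier must be one of {SUPPORT_TIERS}, got {self.support_tier!r}"
            )
        if self.followup_h < 0:
            raise ValidationError(f"followup_h must be >= 0, got {self.followup_h}")
        if self.support_tier != "none":
            if not self.oxygen_therapy:
                raise ValidationError("support_tier beyond none requires oxygen_therapy")
            if self.time_to_support_h is None:
                raise ValidationError("support_tier beyond none requires time_to_support_h")
        if self.time_to_support_h is not None:
            if self.time_to_support_h < 0:
                raise ValidationError("time_to_support_h must be >= 0")
            if self.time_to_support_h > self.followup_h:
                raise ValidationError("time_to_support_h must not exceed followup_h")
        if self.wdf is None and self.wdf_total is None:
            raise ValidationError("either raw WDF items or wdf_total must be present")
        if self.wdf is not None and self.wdf_total is not None:
            if wdf_score(self.wdf) != self.wdf_total:
                raise ValidationError(
                    f"wdf_total={self.wdf_total} disagrees with item sum {wdf_score(self.wdf)}"
                )


def _fmt(x: float | None, decimals: int) -> str:
    return "" if x is None else f"{x:.{decimals}f}"


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the canonical CSV column order."""
    rows = []
    for r in records:
        if r.wdf is None:
            raise ValidationError(
                f"record {r.patient_id}: frame export needs raw WDF items"
                " (use the wdf_total CSV schema directly for totals-only data)"
            )
        rows.append(
            {
                "patient_id": r.patient_id,
                "age_months": r.age_months,
                "sex": r.sex,
                "sao2_room_air": r.sao2_room_air,
                "wdf_wheezing": r.wdf.wheezing,
                "wdf_retractions": r.wdf.retractions,
                "resp_rate": r.wdf.respiratory_rate,
                "heart_rate": r.wdf.heart_rate,
                "wdf_breath_sounds": r.wdf.inspiratory_breath_sounds,
                "wdf_cyanosis": int(r.wdf.cyanosis),
                "blines_gt3_bilat_ant": int(r.lus.blines_gt3_bilateral_anterior),
                "confluent_blines_bilat_ant": int(r.lus.confluent_blines_bilateral_anterior),
                "post_consol_small": int(r.lus.posterior_consolidation_small),
                "post_consol_large": int(r.lus.posterior_consolidation_large),
                "admitted": int(r.admitted),
                "oxygen_therapy": int(r.oxygen_therapy),
                "support_tier": r.support_tier,
                "time_to_support_h": r.time_to_support_h,
                "followup_h": r.followup_h,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    """Write the cohort CSV with deterministic formatting (byte-reproducible)."""
    lines = [",".join(CSV_COLUMNS)]
    for r in records:
        if r.wdf is None:
            raise ValidationError(f"record {r.patient_id}: CSV export needs raw WDF items")
        lines.append(
            ",".join(
                [
                    r.patient_id,
                    _fmt(r.age_months, 2),
                    r.sex,
                    _fmt(r.sao2_room_air, 1),
                    str(r.wdf.wheezing),
                    str(r.wdf.retractions),
                    str(r.wdf.respiratory_rate),
                    str(r.wdf.heart_rate),
                    str(r.wdf.inspiratory_breath_sounds),
                    str(int(r.wdf.cyanosis)),
                    str(int(r.lus.blines_gt3_bilateral_anterior)),
                    str(int(r.lus.confluent_blines_bilateral_anterior)),
                    str(int(r.lus.posterior_consolidation_small)),
                    str(int(r.lus.posterior_consolidation_large)),
                    str(int(r.admitted)),
                    str(int(r.oxygen_therapy)),
                    r.support_tier,
                    _fmt(r.time_to_support_h, 2),
                    _fmt(r.followup_h, 1),
                ]
            )
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _cell(row, col, line_no):
    v = row.get(col)
    if v is None or (isinstance(v, float) and pd.isna(v)) or (isinstance(v, str) and v == ""):
        raise ValidationError(f"row {line_no}: missing value in column {col!r}")
    return v


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    """Parse a cohort DataFrame (CSV schema) into validated PatientRecords."""
    has_items = all(
        c in frame.columns
        for c in ("wdf_wheezing", "wdf_retractions", "resp_rate", "heart_rate",
                  "wdf_breath_sounds", "wdf_cyanosis")
    )
    has_total = "wdf_total" in frame.columns
    if not has_items and not has_total:
        raise ValidationError(
            "cohort needs either the six WDF item columns or a wdf_total column"
        )
    missing = [c for c in _MANDATORY if c not in frame.columns and c != "time_to_support_h"]
    if missing:
        raise ValidationError(f"missing mandatory columns: {missing}")
    known = set(CSV_COLUMNS) | {"wdf_total", "wdf_band", "luscab_total", "high_risk"}
    extra = [c for c in frame.columns if c not in known]
    if extra:
        logger.warning("ignoring unknown columns: %s", extra)

    records: list[PatientRecord] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        line_no = i + 2  # header is line 1
        try:
            wdf = None
            if has_items:
                wdf = WDFItems(
                    wheezing=int(_cell(row, "wdf_wheezing", line_no)),
                    retractions=int(_cell(row, "wdf_retractions", line_no)),
                    respiratory_rate=int(_cell(row, "resp_rate", line_no)),
                    heart_rate=int(_cell(row, "heart_rate", line_no)),
                    inspiratory_breath_sounds=int(_cell(row, "wdf_breath_sounds", line_no)),
                    cyanosis=bool(int(_cell(row, "wdf_cyanosis", line_no))),
                )
            total = None
            if has_total and not pd.isna(row["wdf_total"]):
                total = int(row["wdf_total"])
            lus = LUSFindings(
                blines_gt3_bilateral_anterior=bool(int(_cell(row, "blines_gt3_bilat_ant", line_no))),
                confluent_blines_bilateral_anterior=bool(
                    int(_cell(row, "confluent_blines_bilat_ant", line_no))
                ),
                posterior_consolidation_small=bool(int(_cell(row, "post_consol_small", line_no))),
                posterior_consolidation_large=bool(int(_cell(row, "post_consol_large", line_no))),
            )
            tt = row.get("time_to_support_h")
            time_to_support = None if tt is None or pd.isna(tt) or tt == "" else float(tt)
            records.append(
                PatientRecord(
                    patient_id=str(_cell(row, "patient_id", line_no)),
                    age_months=float(_cell(row, "age_months", line_no)),
                    sex=str(_cell(row, "sex", line_no)),
                    sao2_room_air=float(_cell(row, "sao2_room_air", line_no)),
                    lus=lus,
                    admitted=bool(int(_cell(row, "admitted", line_no))),
                    oxygen_therapy=bool(int(_cell(row, "oxygen_therapy", line_no))),
                    support_tier=str(_cell(row, "support_tier", line_no)),
                    followup_h=float(_cell(row, "followup_h", line_no)),
                    time_to_support_h=time_to_support,
                    wdf=wdf,
                    wdf_total=total,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {line_no}: {exc}" if not str(exc).startswith("row ") else str(exc)) from exc
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"row {line_no}: malformed value ({exc})") from exc
    return records


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; malformed rows are reported by line number."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    return frame_to_cohort(frame)
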