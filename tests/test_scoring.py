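"""Unit and property tests for the WDF and LUSCAB score calculators."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from luscab.scoring import (
    LUSCAB_CUTOFF,
    HighRiskClassifier,
    LUSFindings,
    LuscabScorer,
    ValidationError,
    WDFItems,
    classify_high_risk,
    luscab_score,
    score_frame,
    score_record,
    wdf_band,
    wdf_score,
)


def items(wheeze=0, retr=0, rr=25, hr=100, sounds=0, cyan=False):
    return WDFItems(
        wheezing=wheeze,
        retractions=retr,
        respiratory_rate=rr,
        heart_rate=hr,
        inspiratory_breath_sounds=sounds,
        cyanosis=cyan,
    )


ALL_FINDINGS = LUSFindings(True, True, True, True)
NO_FINDINGS = LUSFindings()


class TestWdfScore:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(), 0),  # every item at its minimum
            (dict(wheeze=3, retr=3, rr=70, hr=130, sounds=3, cyan=True), 14),  # all maxima
            (dict(wheeze=2, retr=1, rr=50, hr=130), 6),  # mixed hand-summed case
        ],
    )
    def test_known_totals(self, kwargs, expected):
        assert wdf_score(items(**kwargs)) == expected

    @pytest.mark.parametrize(
        "rate, points", [(29, 0), (30, 0), (31, 1), (45, 1), (46, 2), (60, 2), (61, 3)]
    )
    def test_respiratory_rate_band_edges(self, rate, points):
        assert wdf_score(items(rr=rate)) == points

    @pytest.mark.parametrize("rate, points", [(119, 0), (120, 0), (121, 1)])
    def test_heart_rate_band_edges(self, rate, points):
        assert wdf_score(items(hr=rate)) == points

    def test_ordinal_out_of_range_names_the_item(self):
        with pytest.raises(ValidationError, match="wheezing"):
            items(wheeze=4)
        with pytest.raises(ValidationError, match="retractions"):
            items(retr=-1)

    @given(
        wheeze=st.integers(0, 3),
        retr=st.integers(0, 3),
        rr=st.integers(0, 120),
        hr=st.integers(0, 250),
        sounds=st.integers(0, 3),
        cyan=st.booleans(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_each_item_and_in_range(self, wheeze, retr, rr, hr, sounds, cyan):
        base = wdf_score(items(wheeze, retr, rr, hr, sounds, cyan))
        assert 0 <= base <= 14
        if wheeze < 3:
            assert wdf_score(items(wheeze + 1, retr, rr, hr, sounds, cyan)) >= base
        assert wdf_score(items(wheeze, retr, rr + 5, hr, sounds, cyan)) >= base
        assert wdf_score(items(wheeze, retr, rr, hr + 5, sounds, cyan)) >= base
        if not cyan:
            assert wdf_score(items(wheeze, retr, rr, hr, sounds, True)) >= base


class TestWdfBand:
    @pytest.mark.parametrize(
        "total, band",
        [(0, "mild"), (2, "mild"), (3, "mild"), (4, "moderate"), (7, "moderate"),
         (8, "severe"), (14, "severe")],
    )
    def test_bands(self, total, band):
        assert wdf_band(total) == band

    @pytest.mark.parametrize("bad", [-1, 15])
    def test_out_of_range(self, bad):
        with pytest.raises(ValidationError):
            wdf_band(bad)


class TestLuscabScore:
    @pytest.mark.parametrize(
        "age, wdf, lus, policy, expected",
        [
            (3.0, 2, NO_FINDINGS, "additive", 0.0),
            (0.8, 7, ALL_FINDINGS, "additive", 10.5),
            (0.8, 7, ALL_FINDINGS, "exclusive_max", 9.5),
            (0.5, 3, NO_FINDINGS, "additive", 1.5),
            (2.0, 6, LUSFindings(posterior_consolidation_large=True), "additive", 5.5),
        ],
    )
    def test_known_totals(self, age, wdf, lus, policy, expected):
        assert luscab_score(age, wdf, lus, policy) == expected

    def test_age_boundary_is_strict(self):
        assert luscab_score(1.0, 0, NO_FINDINGS) == 0.0
        assert luscab_score(0.99, 0, NO_FINDINGS) == 1.5

    def test_negative_age_rejected(self):
        with pytest.raises(ValidationError):
            luscab_score(-0.1, 0, NO_FINDINGS)

    def test_exhaustive_enumeration_range_and_half_steps(self):
        """All 64 item-satisfaction combinations: range and 0.5-multiples."""
        totals = {"additive": set(), "exclusive_max": set()}
        for age_lt1, wdf_ge6, b, c, s, l in itertools.product([False, True], repeat=6):
            lus = LUSFindings(b, c, s, l)
            for policy in totals:
                t = luscab_score(0.5 if age_lt1 else 2.0, 7 if wdf_ge6 else 3, lus, policy)
                assert t * 2 == int(t * 2), "totals must be exact half-point multiples"
                totals[policy].add(t)
        assert max(totals["additive"]) == 10.5
        assert max(totals["exclusive_max"]) == 9.5
        assert min(totals["additive"]) == min(totals["exclusive_max"]) == 0.0

    @given(
        age=st.floats(0, 12, allow_nan=False),
        wdf=st.integers(0, 14),
        flags=st.tuples(*[st.booleans()] * 4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_additive_dominates_exclusive(self, age, wdf, flags):
        lus = LUSFindings(*flags)
        add = luscab_score(age, wdf, lus, "additive")
        exc = luscab_score(age, wdf, lus, "exclusive_max")
        assert add >= exc
        if not (flags[2] and flags[3]):
            assert add == exc


class TestClassifyHighRisk:
    @pytest.mark.parametrize("total, risk", [(3.5, True), (3.0, False), (10.5, True), (0.0, False)])
    def test_cutoff(self, total, risk):
        assert classify_high_risk(total) is risk


class TestScoreRecord:
    def test_consistent_total_and_items_accepted(self):
        res = score_record(2.0, wdf=items(wheeze=2, retr=1, rr=50, hr=130), wdf_total=6)
        assert res.wdf_total == 6 and res.wdf_band == "moderate"
        assert res.luscab_total == 2.5 and res.high_risk is False

    def test_inconsistent_total_rejected(self):
        with pytest.raises(ValidationError, match="disagrees"):
            score_record(2.0, wdf=items(), wdf_total=5)

    def test_total_only_accepted(self):
        res = score_record(0.5, wdf_total=8, lus=NO_FINDINGS)
        assert res.wdf_band == "severe"
        assert res.luscab_total == 1.5 + 2.5


def _toy_frame():
    return pd.DataFrame(
        {
            "age_months": [0.5, 4.0],
            "wdf_wheezing": [2, 0],
            "wdf_retractions": [1, 0],
            "resp_rate": [50, 28],
            "heart_rate": [130, 100],
            "wdf_breath_sounds": [0, 0],
            "wdf_cyanosis": [0, 0],
            "blines_gt3_bilat_ant": [1, 0],
            "confluent_blines_bilat_ant": [0, 0],
            "post_consol_small": [0, 0],
            "post_consol_large": [1, 0],
        }
    )


class TestEstimators:
    def test_scorer_appends_columns(self):
        out = LuscabScorer().fit(_toy_frame()).transform(_toy_frame())
        assert list(out["wdf_total"]) == [6, 0]
        assert list(out["luscab_total"]) == [1.5 + 1.5 + 3 + 2.5, 0.0]
        assert list(out["high_risk"]) == [True, False]

    def test_sklearn_contract_and_pipeline(self):
        pipe = Pipeline([("score", LuscabScorer()), ("risk", HighRiskClassifier())])
        pred = pipe.fit(_toy_frame()).predict(_toy_frame())
        assert list(pred) == [True, False]
        cloned = clone(pipe)
        assert cloned.get_params()["risk__cutoff"] == LUSCAB_CUTOFF
        scorer = LuscabScorer(consolidation_policy="exclusive_max")
        assert clone(scorer).get_params()["consolidation_policy"] == "exclusive_max"

    def test_decision_function_is_the_luscab_total(self):
        clf = HighRiskClassifier().fit(_toy_frame())
        np.testing.assert_allclose(clf.decision_function(_toy_frame()), [8.5, 0.0])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            score_frame(pd.DataFrame({"age_months": [1.0]}))
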