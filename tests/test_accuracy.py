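"""Diagnostic-accuracy tests: 2x2 tables, Se/Sp/PPV/NPV, ROC/AUC, DeLong CI."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from luscab.accuracy import (
    ConfusionMatrix,
    auc_mann_whitney,
    confusion_at_cutoff,
    diagnostic_stats,
    reconstruct_confusion,
    roc_auc,
)
from luscab.scoring import ValidationError

# Printed accuracy rows of the validation study: (Se, Sp, n_pos, n_neg) and
# the published proportions they must reproduce after 2x2 reconstruction.
PRINTED_ROWS = {
    "admission": ((0.515, 0.706, 33, 17), (0.515, 0.706, 0.773, 0.429)),
    "oxygen": ((0.619, 0.690, 21, 29), (0.619, 0.690, 0.590, 0.714)),
    "support": ((0.667, 0.688, 18, 32), (0.667, 0.688, 0.546, 0.786)),
    "ncpap_mv": ((0.875, 0.643, 8, 42), (0.875, 0.643, 0.318, 0.964)),
}


class TestConfusionAtCutoff:
    @pytest.mark.parametrize(
        "scores, outcomes, expected",
        [
            ([5, 4, 3, 1], [True, True, False, False], (2, 0, 2, 0)),
            ([4, 1], [False, True], (0, 1, 0, 1)),
            ([3.5, 3.5, 3.5, 3.5], [True, True, False, False], (2, 2, 0, 0)),
        ],
    )
    def test_toy_tables(self, scores, outcomes, expected):
        cm = confusion_at_cutoff(scores, outcomes, 3.5)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == expected
        assert cm.n == len(scores)

    def test_empty_and_mismatched_inputs(self):
        with pytest.raises(ValidationError):
            confusion_at_cutoff([], [], 3.5)
        with pytest.raises(ValidationError):
            confusion_at_cutoff([1, 2], [True], 3.5)


class TestDiagnosticStats:
    @pytest.mark.parametrize(
        "cm, expected",
        [
            (ConfusionMatrix(tp=7, fn=1, fp=15, tn=27), (0.875, 0.643, 0.318, 0.964)),
            (ConfusionMatrix(tp=17, fn=16, fp=5, tn=12), (0.515, 0.706, 0.773, 0.429)),
            (ConfusionMatrix(tp=5, fn=0, fp=0, tn=5), (1.0, 1.0, 1.0, 1.0)),
        ],
    )
    def test_published_and_perfect_tables(self, cm, expected):
        st_ = diagnostic_stats(cm)
        got = (st_.sensitivity, st_.specificity, st_.ppv, st_.npv)
        assert got == pytest.approx(expected, abs=5e-4)

    def test_zero_denominators_yield_missing(self):
        st_ = diagnostic_stats(ConfusionMatrix(tp=0, fn=0, fp=2, tn=3))
        assert st_.sensitivity is None and st_.npv is not None
        st_ = diagnostic_stats(ConfusionMatrix(tp=3, fn=2, fp=0, tn=0))
        assert st_.specificity is None and st_.ppv is not None

    @given(
        tp=st.integers(0, 200), fp=st.integers(0, 200),
        tn=st.integers(0, 200), fn=st.integers(0, 200),
    )
    @settings(max_examples=300, derandomize=True)
    def test_bayes_identity(self, tp, fp, tn, fn):
        """PPV/NPV follow from Se, Sp and prevalence by Bayes' rule."""
        if tp + fp + tn + fn == 0:
            return
        cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
        s = diagnostic_stats(cm)
        P, N = cm.n_positive, cm.n_negative
        if s.sensitivity is not None and s.specificity is not None:
            if s.ppv is not None:
                assert s.ppv == pytest.approx(
                    s.sensitivity * P / (s.sensitivity * P + (1 - s.specificity) * N), abs=1e-12
                )
            if s.npv is not None:
                assert s.npv == pytest.approx(
                    s.specificity * N / (s.specificity * N + (1 - s.sensitivity) * P), abs=1e-12
                )


class TestReconstructConfusion:
    @pytest.mark.parametrize(
        "se, sp, n_pos, n_neg, expected",
        [
            (0.875, 0.643, 8, 42, (7, 1, 27, 15)),
            (1.0, 1.0, 3, 5, (3, 0, 5, 0)),
            (0.667, 0.688, 18, 32, (12, 6, 22, 10)),
        ],
    )
    def test_known_reconstructions(self, se, sp, n_pos, n_neg, expected):
        cm = reconstruct_confusion(se, sp, n_pos, n_neg)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == expected

    @pytest.mark.parametrize("name", list(PRINTED_ROWS))
    def test_published_rows_round_trip(self, name):
        """Reconstruction then stats reproduces every printed proportion to +/-0.001."""
        (se, sp, n_pos, n_neg), printed = PRINTED_ROWS[name]
        s = diagnostic_stats(reconstruct_confusion(se, sp, n_pos, n_neg))
        for got, want in zip((s.sensitivity, s.specificity, s.ppv, s.npv), printed):
            assert got == pytest.approx(want, abs=1e-3)

    def test_inconsistent_proportion_warns(self, recwarn):
        # Se 0.40 cannot arise from 3 positives (achievable: 0, 1/3, 2/3, 1)
        with pytest.warns(UserWarning, match="inconsistent"):
            reconstruct_confusion(0.40, 0.5, 3, 4)
        # exact and near-exact printed values pass silently
        reconstruct_confusion(0.875, 0.643, 8, 42)
        assert not recwarn.list


class TestRocAuc:
    def test_brute_force_pair_counting(self):
        scores = [3, 5, 1, 2, 4]
        outcomes = [True, True, False, False, False]
        assert auc_mann_whitney(scores, outcomes) == pytest.approx(5 / 6)

    def test_identical_score_multisets_give_half(self):
        scores = [1, 2, 3, 1, 2, 3]
        outcomes = [True, True, True, False, False, False]
        assert auc_mann_whitney(scores, outcomes) == pytest.approx(0.5)

    def test_perfect_separation(self):
        res = roc_auc([4, 5, 1, 2], [True, True, False, False])
        assert res.auc == 1.0
        assert res.auc_ci_high == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            roc_auc([1, 2], [True, True])
        with pytest.raises(ValidationError, match="positive"):
            roc_auc([1, 2], [False, False])

    def test_curve_monotone_with_endpoints(self, rng):
        scores = rng.choice(np.arange(0, 11) / 2, size=60)
        outcomes = rng.random(60) < 0.4
        outcomes[0], outcomes[1] = True, False
        res = roc_auc(scores, outcomes)
        assert res.tpr[0] == res.fpr[0] == 0.0
        assert res.tpr[-1] == res.fpr[-1] == 1.0
        assert np.all(np.diff(res.tpr) >= 0) and np.all(np.diff(res.fpr) >= 0)
        assert res.auc_ci_low <= res.auc <= res.auc_ci_high

    def test_u_statistic_equals_trapezoidal_area(self, rng):
        """Two independent AUC computations must agree to 1e-12."""
        for _ in range(20):
            scores = rng.choice(np.arange(0, 22) / 2, size=40)
            outcomes = rng.random(40) < 0.5
            if outcomes.all() or not outcomes.any():
                continue
            res = roc_auc(scores, outcomes)
            trapezoid = float(np.trapezoid(res.tpr, res.fpr))
            assert res.auc == pytest.approx(trapezoid, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        scores = rng.normal(size=200) + rng.integers(0, 2, 200)
        outcomes = rng.random(200) < 0.5
        outcomes[:2] = [True, False]
        assert auc_mann_whitney(scores, outcomes) == pytest.approx(
            roc_auc_score(outcomes, scores), abs=1e-12
        )

    def test_threshold_sweep_converges_to_analytic_se_sp(self, rng):
        """Empirical Se/Sp at a fixed threshold converge to the normal-model truth."""
        n = 100_000
        outcomes = rng.random(n) < 0.3
        scores = rng.normal(size=n) + outcomes  # positives shifted by +1
        cm = confusion_at_cutoff(scores, outcomes, cutoff=0.5)
        s = diagnostic_stats(cm)
        assert s.sensitivity == pytest.approx(1 - sps.norm.cdf(0.5 - 1), abs=0.01)
        assert s.specificity == pytest.approx(sps.norm.cdf(0.5), abs=0.01)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_delong_ci_matches_r_proc(tmp_path, rng):
    """DeLong 95% CI cross-checked against the pROC reference implementation."""
    scores = np.round(rng.normal(size=80), 3) + rng.integers(0, 2, 80) * 0.8
    outcomes = rng.random(80) < 0.4
    outcomes[:2] = [True, False]
    res = roc_auc(scores, outcomes)
    script = tmp_path / "ci.R"
    script.write_text(
        "suppressMessages(library(pROC))\n"
        f"resp <- c({','.join(str(int(o)) for o in outcomes)})\n"
        f"pred <- c({','.join(repr(float(s)) for s in scores)})\n"
        "r <- roc(resp, pred, quiet=TRUE, direction='<')\n"
        "ci <- ci.auc(r, method='delong')\n"
        "cat(sprintf('%.10f %.10f %.10f', ci[1], ci[2], ci[3]))\n"
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    ).stdout.split()
    lo, auc_r, hi = map(float, out)
    assert res.auc == pytest.approx(auc_r, abs=1e-10)
    assert res.auc_ci_low == pytest.approx(lo, abs=1e-6)
    assert res.auc_ci_high == pytest.approx(hi, abs=1e-6)
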