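"""Confusion-matrix statistics: published worked examples, Wilson
interval properties, and ROC against a pairwise-ranking oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import mann_whitney_auc, wilson_closed_form
from pevol import (
    ConfusionMatrix,
    confusion_matrix,
    mcc,
    metric_set,
    pooled_evaluation,
    roc_by_volume,
    wilson_interval,
)
from pevol.reference import REPORTED


class TestConfusionMatrix:
    def test_tally_partitions_cohort(self):
        cm = confusion_matrix(zip([1, 1, 0, 0], [1, 0, 0, 1]))
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_all_correct(self):
        cm = confusion_matrix(zip([1] * 5 + [0] * 5, [1] * 5 + [0] * 5))
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (5, 5, 0, 0)

    def test_missing_prediction_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            confusion_matrix([(1, None)])

    def test_pooling_is_elementwise_sum(self):
        a = ConfusionMatrix(1, 2, 3, 4)
        b = ConfusionMatrix(10, 0, 0, 0)
        assert (a + b).tp == 11 and (a + b).n == a.n + b.n


class TestMcc:
    @pytest.mark.parametrize(
        "key,expected",
        [
            ("internal_strategy1", 0.849),
            ("internal_baseline", 0.639),
            ("fumpe_strategy1", 0.804),
            ("rspect_strategy1", 0.886),
            ("rspect_baseline", 0.733),
        ],
    )
    def test_published_operating_points(self, key, expected):
        assert mcc(REPORTED[key]) == pytest.approx(expected, abs=5e-4)

    def test_perfect_classifier(self):
        assert mcc(ConfusionMatrix(tp=7, tn=7, fp=0, fn=0)) == 1.0

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0)) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        tn=st.integers(0, 500), fn=st.integers(0, 500),
    )
    def test_bounded_and_matches_sklearn(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        cm = ConfusionMatrix(tp, fp, tn, fn)
        value = mcc(cm)
        assert -1.0 <= value <= 1.0
        import warnings

        from sklearn.metrics import matthews_corrcoef

        y_true = [1] * (tp + fn) + [0] * (tn + fp)
        y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
        with warnings.catch_warnings():
            # single-class degenerate inputs are deliberate here
            warnings.simplefilter("ignore", UserWarning)
            expected = matthews_corrcoef(y_true, y_pred)
        assert value == pytest.approx(expected, abs=1e-12)


class TestWilsonInterval:
    def test_published_sensitivity_ci(self):
        low, high = wilson_interval(123, 128)
        assert round(low * 100) == 91 and round(high * 100) == 98

    def test_published_two_of_two_ci(self):
        low, high = wilson_interval(2, 2)
        assert low == pytest.approx(0.342, abs=5e-4)
        assert high == 1.0

    def test_zero_successes_lower_bound(self):
        low, _ = wilson_interval(0, 50)
        assert low == 0.0

    def test_matches_closed_form(self):
        for k, n in [(0, 1), (1, 1), (5, 10), (123, 128), (521, 551), (379, 385)]:
            assert wilson_interval(k, n) == pytest.approx(
                wilson_closed_form(k, n), abs=1e-10
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_interval(5, 3)
        with pytest.raises(ValueError):
            wilson_interval(0, 0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(n=st.integers(1, 400), data=st.data())
    def test_complement_symmetry_and_containment(self, n, data):
        k = data.draw(st.integers(0, n))
        low, high = wilson_interval(k, n)
        c_low, c_high = wilson_interval(n - k, n)
        assert low == pytest.approx(1.0 - c_high, abs=1e-12)
        assert high == pytest.approx(1.0 - c_low, abs=1e-12)
        assert low <= k / n <= high


class TestMetricSet:
    def test_internal_strategy1_worked_example(self):
        ms = metric_set(REPORTED["internal_strategy1"], bootstrap_reps=0)
        assert ms.sensitivity == pytest.approx(0.961, abs=5e-4)
        assert ms.specificity == pytest.approx(0.946, abs=5e-4)
        assert ms.accuracy == pytest.approx(0.948, abs=5e-4)
        assert ms.balanced_accuracy == pytest.approx(
            (ms.sensitivity + ms.specificity) / 2
        )

    def test_fumpe_strategy1_worked_example(self):
        ms = metric_set(REPORTED["fumpe_strategy1"], bootstrap_reps=0)
        assert ms.mcc == pytest.approx(0.804, abs=5e-4)
        assert ms.specificity == 1.0

    def test_degenerate_single_class(self):
        ms = metric_set(ConfusionMatrix(tp=0, fp=0, tn=9, fn=0), bootstrap_reps=0)
        assert ms.sensitivity is None
        assert ms.specificity == 1.0
        assert "sensitivity" not in ms.ci

    def test_mcc_bootstrap_ci_seeded_and_sane(self):
        cm = REPORTED["internal_strategy1"]
        a = metric_set(cm, seed=3).ci["mcc"]
        b = metric_set(cm, seed=3).ci["mcc"]
        c = metric_set(cm, seed=4).ci["mcc"]
        assert a == b
        assert a != c
        low, high = a
        assert -1.0 <= low <= mcc(cm) <= high <= 1.0

    def test_pooled_combined_dataset(self):
        pooled = pooled_evaluation(
            [
                REPORTED["fumpe_strategy1"],
                REPORTED["rspect_strategy1"],
                ConfusionMatrix(tp=0, fp=30, tn=521, fn=0),
            ],
            bootstrap_reps=0,
        )
        assert pooled.cm.n_positive == 417 and pooled.cm.n_negative == 938
        assert pooled.sensitivity == pytest.approx(410 / 417)
        assert pooled.specificity == pytest.approx(869 / 938)

    def test_pooling_identity_and_scale_invariance(self):
        cm = REPORTED["rspect_strategy1"]
        doubled = pooled_evaluation([cm, cm], bootstrap_reps=0)
        single = metric_set(cm, bootstrap_reps=0)
        assert doubled.sensitivity == pytest.approx(single.sensitivity)
        assert doubled.specificity == pytest.approx(single.specificity)
        assert doubled.mcc == pytest.approx(single.mcc)


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_by_volume([100, 90, 80, 5, 2, 0], [1, 1, 1, 0, 0, 0])
        assert roc.auc == 1.0
        assert roc.fpr[0] == 0.0 and roc.tpr[-1] == 1.0

    def test_all_tied_scores(self):
        roc = roc_by_volume([7.0] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_endpoints_and_monotone(self, rng):
        scores = rng.exponential(50, size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]  # both classes present
        roc = roc_by_volume(scores, labels)
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            roc_by_volume([1.0, 2.0], [1, 1])

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_matches_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80))
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        # quantized scores to force ties
        scores = np.round(rng.exponential(30, size=n) + 20 * labels, -1)
        roc = roc_by_volume(scores, labels)
        assert roc.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        n = 120
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        scores = rng.exponential(30, size=n) + 15 * labels
        roc = roc_by_volume(scores, labels)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
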