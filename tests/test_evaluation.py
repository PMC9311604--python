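"""Metrics against hand arithmetic and scikit-learn / scipy cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn import metrics as skm

from _oracles import wilcoxon_exact_oracle
from mbeegcbam.evaluation import (MetricsReport, cohen_kappa, confusion_matrix,
                                  format_report, precision_recall_f1,
                                  wilcoxon_signed_rank)


class TestConfusionMatrix:
    def test_enumerated_example(self):
        conf = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(conf, [[1, 1], [0, 2]])

    def test_perfect_predictions_are_diagonal(self):
        y = [0, 1, 2, 3, 2, 1]
        conf = confusion_matrix(y, y, 4)
        np.testing.assert_array_equal(conf, np.diag([1, 2, 2, 1]))

    def test_single_predicted_class_is_single_column(self):
        conf = confusion_matrix([0, 1, 2, 3], [2, 2, 2, 2], 4)
        assert conf[:, 2].tolist() == [1, 1, 1, 1]
        assert conf.sum() == 4

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix([0, 1], [0], 2)

    def test_matches_sklearn_on_random_labels(self, rng):
        t = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        np.testing.assert_array_equal(
            confusion_matrix(t, p, 4),
            skm.confusion_matrix(t, p, labels=range(4)))


def balanced_uniform_confusion(accuracy, n=10000):
    """4-class confusion with balanced rows and uniform predicted marginals."""
    per_class = n / 4
    diag = accuracy * per_class
    off = (per_class - diag) / 3
    return np.full((4, 4), off) + np.diag([diag - off] * 4)


class TestCohenKappa:
    def test_perfect_agreement_is_one(self):
        assert cohen_kappa(np.diag([5, 5, 5, 5])) == pytest.approx(1.0)

    def test_two_class_hand_example(self):
        # p_o = 0.75, p_e = 0.5 -> kappa = 0.5
        assert cohen_kappa(np.array([[3, 1], [1, 3]])) == pytest.approx(0.5)

    @pytest.mark.parametrize("accuracy,expected", [
        (0.9109, 0.881),   # 91.09 % under the balanced-marginal identity
        (0.9643, 0.952),   # 96.43 %
    ])
    def test_balanced_marginal_identity_reproduces_reported_kappas(
            self, accuracy, expected):
        kappa = cohen_kappa(balanced_uniform_confusion(accuracy))
        assert round(kappa, 3) == expected
        assert kappa == pytest.approx((accuracy - 0.25) / 0.75)

    def test_degenerate_single_cell_warns_and_returns_zero(self):
        conf = np.zeros((3, 3))
        conf[1, 1] = 10
        with pytest.warns(UserWarning, match="degenerate"):
            assert cohen_kappa(conf) == 0.0

    def test_matches_sklearn_on_random_labels(self, rng):
        t = rng.integers(0, 4, 500)
        p = rng.integers(0, 4, 500)
        ours = cohen_kappa(confusion_matrix(t, p, 4))
        assert ours == pytest.approx(skm.cohen_kappa_score(t, p))

    def test_random_predictor_kappa_centered_on_zero(self):
        rng = np.random.default_rng(0)
        kappas = []
        for _ in range(20):
            t = np.repeat(np.arange(4), 2500)
            p = rng.integers(0, 4, 10000)
            kappas.append(cohen_kappa(confusion_matrix(t, p, 4)))
        assert abs(np.mean(kappas)) < 0.05


class TestPrecisionRecallF1:
    def test_diagonal_confusion_gives_all_ones(self):
        out = precision_recall_f1(np.diag([3, 4, 5, 6]))
        np.testing.assert_allclose(out["precision"], 1.0)
        np.testing.assert_allclose(out["recall"], 1.0)
        assert out["f1"] == pytest.approx(1.0)

    def test_two_class_hand_example(self):
        out = precision_recall_f1(np.array([[3, 1], [1, 3]]))
        np.testing.assert_allclose(out["precision"], [0.75, 0.75])
        np.testing.assert_allclose(out["recall"], [0.75, 0.75])
        assert out["f1"] == pytest.approx(0.75)

    def test_zero_denominator_class_warns_and_contributes_zero(self):
        conf = np.array([[4, 0], [2, 0]])  # class 1 never predicted
        with pytest.warns(UserWarning, match="zero-denominator"):
            out = precision_recall_f1(conf)
        assert out["precision"][1] == 0.0

    def test_matches_sklearn_macro_averages(self, rng):
        t = rng.integers(0, 4, 300)
        p = rng.integers(0, 4, 300)
        out = precision_recall_f1(confusion_matrix(t, p, 4))
        assert out["macro_precision"] == pytest.approx(
            skm.precision_score(t, p, average="macro"))
        assert out["macro_recall"] == pytest.approx(
            skm.recall_score(t, p, average="macro"))
        assert out["macro_f1"] == pytest.approx(
            skm.f1_score(t, p, average="macro"))

    def test_headline_f1_is_harmonic_mean_of_macros(self, rng):
        t = rng.integers(0, 4, 300)
        p = rng.integers(0, 4, 300)
        out = precision_recall_f1(confusion_matrix(t, p, 4))
        mp, mr = out["macro_precision"], out["macro_recall"]
        assert out["f1"] == pytest.approx(2 * mp * mr / (mp + mr))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.integers(0, 3), min_size=1, max_size=100),
       st.randoms(use_true_random=False))
def test_accuracy_from_confusion_equals_match_fraction(y_true, rnd):
    y_pred = [rnd.randint(0, 3) for _ in y_true]
    conf = confusion_matrix(y_true, y_pred, 4)
    acc = np.trace(conf) / conf.sum()
    assert acc == pytest.approx(np.mean(np.array(y_true) == np.array(y_pred)))


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        stat, p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_six_uniform_positive_differences(self):
        a = np.array([10.0, 11, 12, 13, 14, 15])
        b = a - np.array([1.0, 2, 3, 4, 5, 6])
        stat, p = wilcoxon_signed_rank(a, b)
        assert stat == 0.0
        assert p == pytest.approx(2 / 64)  # 0.03125

    def test_exact_p_matches_full_enumeration_oracle(self, rng):
        for seed in range(5):
            d = np.random.default_rng(seed).normal(size=9)
            stat, p = wilcoxon_signed_rank(d, np.zeros(9))
            assert p == pytest.approx(wilcoxon_exact_oracle(d))

    def test_exact_p_matches_scipy_on_tie_free_data(self, rng):
        a = rng.normal(size=14)
        b = rng.normal(size=14)
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(sps.wilcoxon(a, b, mode="exact").pvalue)

    def test_tied_magnitudes_use_average_ranks(self):
        # d = (+1, -1, +2): ranks (1.5, 1.5, 3); W+ = 4.5
        stat, p = wilcoxon_signed_rank([1.0, -1.0, 2.0], [0.0, 0.0, 0.0])
        assert stat == 1.5
        assert p == pytest.approx(wilcoxon_exact_oracle([1.0, -1.0, 2.0]))

    def test_large_sample_normal_approximation(self, rng):
        a = rng.normal(0.4, 1.0, size=40)
        b = rng.normal(0.0, 1.0, size=40)
        _, p = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, mode="approx", correction=True).pvalue
        assert p == pytest.approx(ref, abs=0.01)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


def test_metrics_report_and_format(rng):
    t = rng.integers(0, 4, 120)
    p = np.where(rng.random(120) < 0.8, t, rng.integers(0, 4, 120))
    report = MetricsReport.from_predictions(t, p, 4)
    assert report.confusion.sum() == 120
    assert report.accuracy == pytest.approx(np.mean(t == p))
    d = report.to_dict()
    assert set(d) >= {"confusion", "accuracy", "kappa", "f1"}
    text = format_report(report)
    for name in ("LH", "RH", "F", "Tou", "Accuracy", "K value"):
        assert name in text
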