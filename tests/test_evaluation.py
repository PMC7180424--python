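import numpy as np
import pandas as pd
import pytest

from polypscope.evaluation import (
    confusion_matrix,
    evaluate,
    majority_vote,
    mean_metrics,
    mean_pairwise_kappa,
    multiclass_kappa,
    per_class_metrics,
    report_round,
    two_proportion_test,
    wald_ci,
)
from polypscope.wsi_io import SLIDE_CLASSES


def make_panel(vote_lists, annotators=("a1", "a2", "a3", "a4", "a5")):
    rows = []
    for i, votes in enumerate(vote_lists):
        for aid, lab in zip(annotators, votes):
            rows.append({"slide_id": f"s{i}", "annotator_id": aid, "label": lab})
    return pd.DataFrame(rows)


class TestMajorityVote:
    def test_plurality_winner(self):
        panel = make_panel([("TA", "TA", "TA", "HP", "SSA")])
        result = majority_vote(panel)
        assert result.loc[0, "label"] == "TA" and not result.loc[0, "tie"]

    def test_tie_resolved_by_reference_annotator(self):
        panel = make_panel([("TA", "TA", "HP", "HP", "SSA")])
        result = majority_vote(panel, reference_annotator="a3")  # voted HP
        assert result.loc[0, "label"] == "HP" and result.loc[0, "tie"]

    def test_unanimous_panels(self):
        panel = make_panel([("TVA",) * 5, ("SSA",) * 5])
        result = majority_vote(panel)
        assert list(result["label"]) == ["TVA", "SSA"]
        assert not result["tie"].any()

    def test_missing_label_names_slide_and_annotator(self):
        panel = make_panel([("TA",) * 5, ("HP",) * 5]).iloc[:-1]  # drop a5 on s1
        with pytest.raises(ValueError, match="s1.*a5"):
            majority_vote(panel)


class TestPerClassMetrics:
    def test_perfect_predictions(self):
        labels = np.array(SLIDE_CLASSES * 3)
        for cls in SLIDE_CLASSES:
            m = per_class_metrics(labels, labels, cls)
            assert (m.accuracy, m.sensitivity, m.specificity) == (100.0, 100.0, 100.0)

    def test_hand_counted_two_by_two(self):
        truth = ["TA", "TA", "HP", "HP"]
        pred = ["TA", "HP", "HP", "HP"]
        m = per_class_metrics(pred, truth, "TA")
        assert (m.sensitivity, m.specificity, m.accuracy) == (50.0, 100.0, 75.0)

    def test_absent_class_reports_missing_not_zero(self):
        truth = ["TA", "TA"]
        pred = ["TA", "TVA"]
        m = per_class_metrics(pred, truth, "SSA")
        assert m.sensitivity is None and m.specificity is not None

    def test_no_negatives_gives_missing_specificity(self):
        truth = ["TA", "TA"]
        m = per_class_metrics(["TA", "TA"], truth, "TA")
        assert m.specificity is None

    def test_matches_brute_force_tabulation(self):
        """Random label vectors: one-vs-rest metrics agree with an explicit
        2x2 tabulation."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 50))
            truth = rng.choice(SLIDE_CLASSES, n)
            pred = rng.choice(SLIDE_CLASSES, n)
            for cls in SLIDE_CLASSES:
                tp = sum(1 for p, t in zip(pred, truth) if p == cls and t == cls)
                fp = sum(1 for p, t in zip(pred, truth) if p == cls and t != cls)
                fn = sum(1 for p, t in zip(pred, truth) if p != cls and t == cls)
                tn = n - tp - fp - fn
                m = per_class_metrics(pred, truth, cls)
                assert m.accuracy == pytest.approx(100 * (tp + tn) / n)
                if tp + fn:
                    assert m.sensitivity == pytest.approx(100 * tp / (tp + fn))
                if tn + fp:
                    assert m.specificity == pytest.approx(100 * tn / (tn + fp))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import recall_score

        rng = np.random.default_rng(1)
        truth = rng.choice(SLIDE_CLASSES, 100)
        pred = rng.choice(SLIDE_CLASSES, 100)
        for cls in SLIDE_CLASSES:
            m = per_class_metrics(pred, truth, cls)
            sk_sens = 100 * recall_score(truth == cls, pred == cls, zero_division=0)
            assert m.sensitivity == pytest.approx(sk_sens)


class TestMeanMetrics:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((93.0, 95.5, 92.4, 93.0), 93.5),   # internal model accuracy row
            ((84.5, 89.5, 85.3, 88.7), 87.0),   # external model accuracy row
            ((89.8, 94.3, 89.8, 91.7), 91.4),   # internal pathologist accuracy row
            ((50.0, 50.0, 50.0, 50.0), 50.0),
        ],
    )
    def test_mean_rows(self, values, expected):
        assert report_round(mean_metrics(values)) == expected

    def test_missing_value_propagates(self):
        assert mean_metrics([90.0, None, 80.0, 70.0]) is None

    def test_rounding_half_away_from_zero(self):
        assert report_round(93.45) == 93.5
        assert report_round(93.44) == 93.4
        assert report_round(-1.25, 1) == -1.3


class TestWaldCI:
    @pytest.mark.parametrize(
        "p,n,lo,hi",
        [
            (0.935, 157, 89.6, 97.4),
            (0.870, 238, 82.7, 91.3),
        ],
    )
    def test_reported_intervals(self, p, n, lo, hi):
        got = wald_ci(p, n)
        assert report_round(got[0]) == lo and report_round(got[1]) == hi

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_proportion_zero_width(self, p):
        lo, hi = wald_ci(p, 50)
        assert lo == hi == 100.0 * p

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0.5, 0)


class TestKappa:
    def test_identical_vectors(self):
        assert multiclass_kappa(["TA", "HP", "SSA"], ["TA", "HP", "SSA"]) == 1.0

    def test_hand_computed_zero(self):
        # p_o = 0.5; marginals a: (TA .5, HP .5), b: (TA .5, HP .5) -> p_e = 0.5
        a = ["TA", "TA", "HP", "HP"]
        b = ["TA", "HP", "TA", "HP"]
        assert multiclass_kappa(a, b) == pytest.approx(0.0)

    def test_degenerate_constant_raters(self):
        assert multiclass_kappa(["TA"] * 5, ["TA"] * 5) == 1.0

    def test_matches_sklearn_on_random_vectors(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            a = rng.choice(SLIDE_CLASSES, n)
            b = rng.choice(SLIDE_CLASSES, n)
            if len(set(a) | set(b)) < 2:
                continue
            assert multiclass_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    def test_binary_collapse_equals_two_class_kappa(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        a4 = rng.choice(SLIDE_CLASSES, 200)
        b4 = rng.choice(SLIDE_CLASSES, 200)
        collapse = np.vectorize(lambda c: "ADEN" if c in ("TA", "TVA") else "SERR")
        a2, b2 = collapse(a4), collapse(b4)
        assert multiclass_kappa(a2, b2) == pytest.approx(cohen_kappa_score(a2, b2))

    def test_identity_panel_mean_kappa_one(self):
        panel = make_panel([("TA",) * 5, ("HP",) * 5, ("SSA",) * 5])
        result = mean_pairwise_kappa(panel)
        assert result.mean == 1.0
        assert len(result.pairwise) == 10  # C(5,2)


class TestTwoProportionTest:
    def test_equal_proportions(self):
        z, p = two_proportion_test(0.5, 100, 0.5, 100)
        assert z == 0.0 and p == 1.0

    def test_reported_external_accuracy_comparison(self):
        _, p = two_proportion_test(0.866, 238, 0.870, 238)
        assert round(p, 2) == 0.90

    def test_continuity_toward_equality(self):
        prev = 0.0
        for eps in (0.01, 0.001, 0.0001):
            _, p = two_proportion_test(0.5, 1000, 0.5 + eps, 1000)
            assert p > prev
            prev = p
        assert p > 0.99

    def test_matches_statsmodels_pooled_z(self):
        from statsmodels.stats.proportion import proportions_ztest

        n1, n2, k1, k2 = 200, 150, 120, 105
        z_sm, p_sm = proportions_ztest([k1, k2], [n1, n2])
        z, p = two_proportion_test(k1 / n1, n1, k2 / n2, n2)
        assert z == pytest.approx(z_sm) and p == pytest.approx(p_sm)

    def test_degenerate_pooled_variance(self):
        z, p = two_proportion_test(0.0, 10, 0.0, 10)
        assert p == 1.0


class TestConfusionMatrix:
    def test_perfect_predictions_identity_ratios(self):
        labels = np.array(SLIDE_CLASSES * 4)
        cm = confusion_matrix(labels, labels)
        np.testing.assert_allclose(cm.ratios, np.eye(4))

    def test_half_split_row(self):
        truth = ["TA"] * 10
        pred = ["TA"] * 5 + ["TVA"] * 5
        cm = confusion_matrix(pred, truth)
        np.testing.assert_allclose(cm.ratios[0], [0.5, 0.5, 0, 0])

    def test_row_sums_one_for_nonempty_rows(self):
        rng = np.random.default_rng(4)
        truth = rng.choice(SLIDE_CLASSES, 80)
        pred = rng.choice(SLIDE_CLASSES, 80)
        cm = confusion_matrix(pred, truth)
        nonempty = cm.counts.sum(axis=1) > 0
        np.testing.assert_allclose(cm.ratios[nonempty].sum(axis=1), 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [])

    def test_matches_sklearn_counts(self):
        from sklearn.metrics import confusion_matrix as sk_cm

        rng = np.random.default_rng(5)
        truth = rng.choice(SLIDE_CLASSES, 120)
        pred = rng.choice(SLIDE_CLASSES, 120)
        np.testing.assert_array_equal(
            confusion_matrix(pred, truth).counts,
            sk_cm(truth, pred, labels=list(SLIDE_CLASSES)))


class TestEvaluateReport:
    def test_perfect_report(self):
        labels = np.array(SLIDE_CLASSES * 10)
        report = evaluate(labels, labels)
        assert report.mean_accuracy == 100.0
        assert report.ci_accuracy == (100.0, 100.0)
        df = report.to_dataframe()
        assert list(df["class"]) == list(SLIDE_CLASSES) + ["Mean"]
        assert (df["accuracy"] == 100.0).all()

    def test_report_mean_equals_mean_of_per_class(self):
        rng = np.random.default_rng(6)
        truth = rng.choice(SLIDE_CLASSES, 60)
        pred = rng.choice(SLIDE_CLASSES, 60)
        report = evaluate(pred, truth)
        per = [report.per_class[c].accuracy for c in SLIDE_CLASSES]
        assert report.mean_accuracy == pytest.approx(np.mean(per))
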