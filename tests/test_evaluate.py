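"""Confusion matrices, diagnostic metrics, group-difference tests."""

import numpy as np
import pytest

from parotid_dx.evaluate import (
    REFERENCE_METHOD_CONFUSIONS,
    BinaryConfusion,
    Metric,
    anova_by_group,
    assemble_comparison_table,
    chi_square_table,
    confusion_from_predictions,
    metrics_from_confusion,
    per_class_metrics,
)


class TestConfusionFromPredictions:
    def test_all_correct(self):
        truth = ["malignant"] * 3 + ["benign"] * 5
        c = confusion_from_predictions(truth, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 0, 5, 0)
        assert c.nd_pos == c.nd_neg == 0

    def test_reference_cohort_counts(self):
        truth = ["malignant"] * 8 + ["benign"] * 28
        pred = ["malignant"] * 8 + ["malignant"] * 2 + ["benign"] * 26
        c = confusion_from_predictions(truth, pred)
        assert (c.tp, c.fn, c.tn, c.fp) == (8, 0, 26, 2)

    def test_non_diagnostic_routed_by_truth(self):
        c = confusion_from_predictions(
            ["benign", "malignant"], ["nd", "nd"], nd_label="nd")
        assert (c.nd_neg, c.nd_pos) == (1, 1)
        assert c.total == 2

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion_from_predictions(["benign"], ["weird"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            BinaryConfusion(tp=-1, fp=0, tn=0, fn=0)


class TestMetrics:
    def test_mri_algorithm_row(self):
        m = metrics_from_confusion(BinaryConfusion(tp=8, fp=2, tn=26, fn=0))
        assert m.percents() == {"sens": 100, "spec": 93, "ppv": 80,
                                "npv": 100, "acc": 94}

    def test_fnac_row_with_non_diagnostic_results(self):
        m = metrics_from_confusion(
            BinaryConfusion(tp=5, fp=1, tn=18, fn=3, nd_pos=0, nd_neg=4))
        assert m.percents() == {"sens": 63, "spec": 78, "ppv": 83,
                                "npv": 86, "acc": 74}
        assert (m.sens.numerator, m.sens.denominator) == (5, 8)
        assert (m.spec.numerator, m.spec.denominator) == (18, 23)
        assert (m.acc.numerator, m.acc.denominator) == (23, 31)

    def test_undefined_metric_is_none_not_zero(self):
        m = metrics_from_confusion(BinaryConfusion(tp=0, fp=0, tn=5, fn=0))
        assert m.spec.percent == 100
        assert m.sens.percent is None
        assert not m.sens.defined

    @pytest.mark.parametrize("num,den,expected", [
        (5, 8, 63), (18, 23, 78), (13, 15, 87),  # printed half-up roundings
        (1, 2, 50), (1, 3, 33), (2, 3, 67), (1, 8, 13),
    ])
    def test_half_up_rounding(self, num, den, expected):
        assert Metric(num, den).percent == expected

    def test_accuracy_identity_without_nd(self):
        # acc = (sens*P + spec*N) / (P + N) when nothing is non-diagnostic
        c = BinaryConfusion(tp=7, fp=3, tn=19, fn=2)
        m = metrics_from_confusion(c)
        P, N = c.tp + c.fn, c.tn + c.fp
        assert m.acc.value == pytest.approx(
            (m.sens.value * P + m.spec.value * N) / (P + N))

    def test_oracle_equivalence_on_random_cohorts(self, rng):
        """metrics_from_confusion agrees with an independent recount
        (sklearn's confusion matrix) over 1,000 random label vectors."""
        from sklearn.metrics import confusion_matrix

        labels = ["benign", "malignant"]
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            truth = rng.choice(labels, n)
            pred = rng.choice(labels, n)
            c = confusion_from_predictions(truth, pred)
            tn, fp, fn, tp = confusion_matrix(
                truth, pred, labels=labels).ravel()
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
            m = metrics_from_confusion(c)
            assert m.acc.value == pytest.approx((tp + tn) / n)
            if tp + fn:
                assert m.sens.value == pytest.approx(tp / (tp + fn))


class TestPerClassMetrics:
    def test_pa_one_vs_rest_reference_counts(self):
        truth = ["PA"] * 14 + ["WT"] * 10 + ["OBT"] * 4 + ["MT"] * 8
        pred = (["PA"] * 13 + ["MT"]        # 13 of 14 PA found
                + ["WT"] * 10
                + ["PA", "PA", "OBT", "MT"]  # 2 OBT called PA
                + ["MT"] * 8)
        m = per_class_metrics(truth, pred, "PA")
        assert m.percents() == {"sens": 93, "spec": 91, "ppv": 87,
                                "npv": 95, "acc": 92}

    def test_perfect_target_class(self):
        truth = pred = ["WT"] * 10 + ["PA"] * 26
        m = per_class_metrics(truth, pred, "WT")
        assert all(v == 100 for v in m.percents().values())

    def test_target_never_predicted_has_undefined_ppv(self):
        truth = ["PA", "WT", "WT"]
        pred = ["WT", "WT", "WT"]
        m = per_class_metrics(truth, pred, "PA")
        assert m.ppv.percent is None


class TestGroupTests:
    def test_protein_cyst_contingency_is_significant(self):
        stat, p = chi_square_table([[5, 9], [10, 0], [3, 5]])
        assert p < 0.005

    def test_ghosting_contingency_is_highly_significant(self):
        stat, p = chi_square_table([[0, 14], [10, 0], [0, 8]])
        assert p < 0.001

    def test_identical_proportions_not_significant(self):
        stat, p = chi_square_table([[10, 10], [10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_table([[0, 5], [0, 7]])

    def test_anova_separates_group_means(self, rng):
        values = np.concatenate([rng.normal(5.3, 1.1, 14),
                                 rng.normal(2.4, 0.4, 10),
                                 rng.normal(2.3, 0.7, 8)])
        groups = np.array(["PA"] * 14 + ["WT"] * 10 + ["MT"] * 8)
        _, p = anova_by_group(values, groups)
        assert p < 0.001

    def test_anova_needs_two_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            anova_by_group([1.0, 2.0], ["PA", "PA"])


class TestComparisonTable:
    def test_reference_methods_rows(self):
        table = assemble_comparison_table(REFERENCE_METHOD_CONFUSIONS)
        assert list(table.loc["MRI algorithm"]) == [100, 93, 80, 100, 94]
        assert list(table.loc["DCE + DWI"]) == [75, 86, 60, 92, 83]
        assert list(table.loc["FNAC"]) == [63, 78, 83, 86, 74]

    def test_single_method(self):
        table = assemble_comparison_table(
            {"only": BinaryConfusion(tp=1, fp=0, tn=1, fn=0)})
        assert len(table) == 1

    def test_empty_confusion_yields_missing_values(self):
        table = assemble_comparison_table(
            {"empty": BinaryConfusion(tp=0, fp=0, tn=0, fn=0)})
        assert table.loc["empty"].isna().all()

    def test_no_methods_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            assemble_comparison_table({})
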