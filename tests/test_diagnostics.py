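"""Confusion matrix, one-vs-rest metrics, CC-Wald CIs, Youden, kappa."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import cohen_kappa_score

from edscreen import (
    BroadCategory,
    ConfusionMatrix4,
    PatientRecord,
    ScoffResponse,
    Sex,
    ValidationError,
    build_confusion,
    cohen_kappa,
    evaluate_all,
    map_dsm5_to_broad,
    proportion_ci,
    sensitivity,
    specificity,
    wald_cc_ci,
    youden,
)
from edscreen.core import Dsm5Diagnosis
from edscreen.rules import ClassificationStatus, classify

RD, BD, HD, OED = BroadCategory


class TestReferenceMatrixValues:
    """Frozen operating characteristics of the published validation matrix."""

    def test_sensitivities(self, reference_cm):
        expected = {RD: (50, 65), BD: (27, 39), HD: (67, 84), OED: (3, 18)}
        for cat, (num, den) in expected.items():
            ci = sensitivity(reference_cm, cat)
            assert (ci.numerator, ci.denominator) == (num, den)
            assert ci.estimate == pytest.approx(num / den)

    def test_specificities(self, reference_cm):
        expected = {RD: (136, 141), BD: (146, 167), HD: (107, 122), OED: (170, 188)}
        for cat, (num, den) in expected.items():
            ci = specificity(reference_cm, cat)
            assert (ci.numerator, ci.denominator) == (num, den)

    def test_confidence_intervals_to_printed_decimal(self, reference_cm):
        sens_ci = {RD: (65.9, 87.9), BD: (53.5, 85.0), HD: (70.6, 88.9),
                   OED: (0.0, 36.7)}
        spec_ci = {RD: (93.0, 99.9), BD: (82.1, 92.8), HD: (81.5, 93.9),
                   OED: (86.0, 94.9)}
        for cat in BroadCategory:
            s = sensitivity(reference_cm, cat)
            assert round(s.lower * 100, 1) == sens_ci[cat][0]
            assert round(s.upper * 100, 1) == sens_ci[cat][1]
            p = specificity(reference_cm, cat)
            assert round(p.lower * 100, 1) == spec_ci[cat][0]
            assert round(p.upper * 100, 1) == spec_ci[cat][1]

    def test_youden_indices(self, reference_cm):
        expected = {RD: 0.73, BD: 0.57, HD: 0.67, OED: 0.07}
        for cat, j in expected.items():
            assert round(youden(reference_cm, cat), 2) == j

    def test_kappa_decomposition(self, reference_cm):
        k = cohen_kappa(reference_cm)
        assert k.po == pytest.approx(147 / 206)
        assert k.pe == pytest.approx(float(Fraction(12713, 42436)))
        assert round(k.kappa, 2) == 0.59
        assert k.lower < k.kappa < k.upper

    def test_render_matches_printed_layout(self, reference_cm):
        text = evaluate_all(reference_cm).render()
        assert "27/39-69.2%" in text
        assert "(65.9-87.9)" in text
        for j in ("0.73", "0.57", "0.67", "0.07"):
            assert j in text
        assert "kappa 0.59" in text


class TestWaldCC:
    def test_lower_truncated_at_zero(self):
        ci = wald_cc_ci(3, 18)
        assert ci.lower == 0.0
        assert round(ci.upper * 100, 1) == 36.7

    def test_upper_truncated_at_one(self):
        assert wald_cc_ci(10, 10).upper == 1.0

    def test_reference_interval(self):
        ci = wald_cc_ci(50, 65)
        assert round(ci.lower * 100, 1) == 65.9
        assert round(ci.upper * 100, 1) == 87.9

    @given(st.integers(min_value=1, max_value=500), st.data())
    def test_bounds_ordered_and_in_unit_interval(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        ci = wald_cc_ci(k, n)
        assert 0 <= ci.lower <= ci.estimate <= ci.upper <= 1

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            wald_cc_ci(5, 3)
        with pytest.raises(ValidationError):
            wald_cc_ci(-1, 10)

    def test_alternative_methods_differ_from_cc_wald(self):
        cc = wald_cc_ci(50, 65)
        for method in ("wald", "wilson", "clopper-pearson"):
            alt = proportion_ci(50, 65, method=method)
            assert alt.estimate == cc.estimate
            assert (alt.lower, alt.upper) != (cc.lower, cc.upper)


class TestKappa:
    def test_diagonal_matrix_gives_one(self):
        cm = ConfusionMatrix4(np.diag([5, 7, 11, 3]))
        assert cohen_kappa(cm).kappa == pytest.approx(1.0)

    def test_independence_matrix_gives_zero(self):
        # all entries r_i * c_j / n are exact integers here
        rows = np.array([20, 30, 40, 10])
        cols = np.array([10, 20, 30, 40])
        cm = ConfusionMatrix4(np.outer(rows, cols) // 100)
        assert cohen_kappa(cm).kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_on_random_labels(self):
        """Independent oracle: sklearn's kappa on the raw label pairs."""
        rng = np.random.default_rng(7)
        cats = list(BroadCategory)
        for _ in range(20):
            truth = rng.integers(0, 4, size=200)
            pred = np.where(rng.random(200) < 0.6, truth, rng.integers(0, 4, 200))
            cm = ConfusionMatrix4.from_labels(
                [cats[i] for i in truth], [cats[i] for i in pred]
            )
            assert cohen_kappa(cm).kappa == pytest.approx(
                cohen_kappa_score(truth, pred)
            )

    def test_kappa_bounded_by_observed_agreement(self, reference_cm):
        k = cohen_kappa(reference_cm)
        assert k.kappa <= k.po

    def test_degenerate_margins_rejected(self):
        cm = ConfusionMatrix4(np.array([[10, 0, 0, 0]] * 1 + [[0, 0, 0, 0]] * 3))
        with pytest.raises(ValidationError, match="degenerate"):
            cohen_kappa(cm)


class TestMatrixInvariants:
    @given(st.integers(min_value=0, max_value=2**31))
    def test_tn_identity(self, seed):
        """TP + FN + FP + TN = n for every category, random matrices."""
        rng = np.random.default_rng(seed)
        cm = ConfusionMatrix4(rng.integers(1, 30, size=(4, 4)))
        frame = evaluate_all(cm).to_frame()
        assert (frame.tp + frame.fn + frame.fp + frame.tn == cm.n).all()
        assert frame.tp.sum() == cm.trace

    def test_youden_invariant_to_count_scaling(self, reference_cm):
        scaled = ConfusionMatrix4(reference_cm.counts * 7)
        for cat in BroadCategory:
            assert youden(scaled, cat) == pytest.approx(youden(reference_cm, cat))

    def test_undefined_sensitivity_raises(self):
        cm = ConfusionMatrix4(
            np.array([[5, 1, 0, 0], [1, 5, 0, 0], [0, 0, 5, 0], [0, 0, 0, 0]])
        )
        with pytest.raises(ValidationError, match="undefined sensitivity"):
            sensitivity(cm, OED)


class TestBuildConfusion:
    def test_reference_cohort_reproduces_published_margins(
        self, reference_cohort, table
    ):
        cm = build_confusion(reference_cohort, table)
        assert [cm.row_total(c) for c in BroadCategory] == [65, 39, 84, 18]
        assert [cm.col_total(c) for c in BroadCategory] == [55, 48, 82, 21]
        assert cm.n == 206

    def test_single_agreeing_record(self, table):
        rec = PatientRecord(
            id="A", sex=Sex.FEMALE, age=25, bmi=16.5,
            scoff=ScoffResponse.from_pattern((0, 0, 1, 1, 0)),
            dsm5=Dsm5Diagnosis.ANOREXIA_NERVOSA,
        )
        cm = build_confusion([rec], table)
        assert cm.counts[0, 0] == 1 and cm.n == 1

    def test_empty_cohort_rejected(self, table):
        with pytest.raises(ValidationError, match="empty"):
            build_confusion([], table)

    def test_undiagnosed_record_listed(self, table):
        rec = PatientRecord(
            id="NODX", sex=Sex.FEMALE, age=25, bmi=21,
            scoff=ScoffResponse.from_pattern((1, 1, 0, 0, 0)),
        )
        with pytest.raises(ValidationError, match="NODX"):
            build_confusion([rec], table)

    def test_screen_negative_record_rejected(self, table):
        rec = PatientRecord(
            id="NEG", sex=Sex.FEMALE, age=25, bmi=21,
            scoff=ScoffResponse.from_pattern((1, 0, 0, 0, 0)),
            dsm5=Dsm5Diagnosis.BULIMIA_NERVOSA,
        )
        with pytest.raises(ValidationError, match="NEG"):
            build_confusion([rec], table)


def per_record_metrics(records, table, cat):
    """Independent oracle: sensitivity/specificity by direct counting."""
    tp = fn = fp = tn = 0
    for rec in records:
        truth = map_dsm5_to_broad(rec.dsm5)
        result = classify(rec.scoff, rec.bmi, table)
        assert result.status is ClassificationStatus.CLASSIFIED
        predicted = result.category
        if truth is cat:
            tp += predicted is cat
            fn += predicted is not cat
        else:
            fp += predicted is cat
            tn += predicted is not cat
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    return sens, spec


def test_matrix_metrics_equal_per_record_counting(reference_cohort, table):
    """Metrics from the tallied matrix equal direct per-record counts."""
    cm = build_confusion(reference_cohort, table)
    for cat in BroadCategory:
        sens, spec = per_record_metrics(reference_cohort, table, cat)
        assert sensitivity(cm, cat).estimate == pytest.approx(sens)
        assert specificity(cm, cat).estimate == pytest.approx(spec)
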