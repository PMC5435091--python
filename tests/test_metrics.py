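import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copdemr import (
    ConfusionMatrix,
    EvaluationError,
    UndefinedMetricError,
    build_confusion,
    build_report,
    catalog_algorithms,
    cohens_kappa,
    predicted_prevalence,
    proportion_with_ci,
    ratio_metrics,
    round_half_up,
    row_from_confusion,
)

from .conftest import make_chart


class TestProportionCI:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (280, 364, (76.9, 72.2, 81.2)),  # final-algorithm sensitivity
            (205, 216, (94.9, 91.1, 97.4)),  # CPP PPV
            (364, 5889, (6.2, 5.6, 6.8)),    # cohort prevalence
        ],
    )
    def test_published_intervals(self, k, n, expected):
        assert proportion_with_ci(k, n).rounded(1) == expected

    def test_boundary_cases(self):
        assert proportion_with_ci(0, 10).ci_low == 0.0
        assert proportion_with_ci(10, 10).ci_high == 100.0

    def test_n_zero_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            proportion_with_ci(0, 0)

    @pytest.mark.parametrize("k,n", [(3, 17), (0, 8), (8, 8), (50, 120), (1, 1000)])
    def test_against_statsmodels_exact_interval(self, k, n):
        """Independent oracle: statsmodels' beta (Clopper-Pearson) interval."""
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
        est = proportion_with_ci(k, n)
        assert est.ci_low == pytest.approx(100 * (0.0 if np.isnan(lo) else lo), abs=1e-9)
        assert est.ci_high == pytest.approx(100 * (1.0 if np.isnan(hi) else hi), abs=1e-9)

    @given(k=st.integers(0, 50), n=st.integers(1, 50))
    @settings(max_examples=200, deadline=None)
    def test_interval_contains_point(self, k, n):
        if k > n:
            return
        est = proportion_with_ci(k, n)
        assert est.ci_low <= est.value <= est.ci_high

    def test_width_shrinks_with_n_at_fixed_rate(self):
        widths = [
            (lambda e: e.ci_high - e.ci_low)(proportion_with_ci(4 * m, 5 * m))
            for m in (2, 8, 32, 128)
        ]
        assert widths == sorted(widths, reverse=True)


class TestRatioMetrics:
    def test_final_algorithm_row(self):
        r = ratio_metrics(ConfusionMatrix(tp=280, fp=19, fn=84, tn=5506))
        assert r.lr_pos.rounded(1) == (223.7, 142.3, 351.6)
        assert r.lr_neg.rounded(2) == (0.23, 0.19, 0.28)
        assert r.dor.rounded(1) == (966.0, 578.8, 1612.1)

    def test_cpp_row_dor(self):
        r = ratio_metrics(ConfusionMatrix(tp=205, fp=11, fn=159, tn=5514))
        assert r.dor.rounded(1) == (646.3, 345.3, 1209.6)

    def test_unit_matrix_is_symmetric(self):
        r = ratio_metrics(ConfusionMatrix(tp=1, fp=1, fn=1, tn=1))
        assert r.lr_pos.value == pytest.approx(1.0)
        assert r.lr_neg.value == pytest.approx(1.0)
        assert r.dor.value == pytest.approx(1.0)

    def test_zero_cell_policy_flags_and_corrects(self):
        cm = ConfusionMatrix(tp=10, fp=0, fn=5, tn=100)
        r = ratio_metrics(cm)
        # fp=0: LR+ and DOR need Haldane-Anscombe; LR- cells are intact
        assert r.lr_pos.corrected and r.dor.corrected and not r.lr_neg.corrected
        assert math.isfinite(r.lr_pos.value) and math.isfinite(r.dor.value)
        # proportions never receive the correction
        assert row_from_confusion("x", cm).specificity.value == 100.0

    @given(
        tp=st.integers(1, 400), fp=st.integers(1, 400),
        fn=st.integers(1, 400), tn=st.integers(1, 4000),
    )
    @settings(max_examples=200, deadline=None)
    def test_dor_equals_lr_ratio(self, tp, fp, fn, tn):
        r = ratio_metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        assert r.dor.value == pytest.approx(r.lr_pos.value / r.lr_neg.value, rel=1e-9)

    @given(
        tp=st.integers(1, 300), fp=st.integers(1, 300),
        fn=st.integers(1, 300), tn=st.integers(1, 300),
    )
    @settings(max_examples=200, deadline=None)
    def test_case_noncase_swap_symmetry(self, tp, fp, fn, tn):
        """Swapping cases and non-cases exchanges sensitivity/specificity
        and leaves the DOR invariant."""
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        sw = cm.swapped()
        a, b = row_from_confusion("a", cm), row_from_confusion("b", sw)
        assert a.sensitivity.value == pytest.approx(b.specificity.value)
        assert a.specificity.value == pytest.approx(b.sensitivity.value)
        assert a.dor.value == pytest.approx(b.dor.value)


class TestPredictedPrevalence:
    def test_alternative_algorithm(self):
        cm = ConfusionMatrix(tp=288, fp=42, fn=76, tn=5483)
        assert round_half_up(predicted_prevalence(cm, 5889), 1) == 5.6

    def test_zero_positives(self):
        cm = ConfusionMatrix(tp=0, fp=0, fn=4, tn=6)
        assert predicted_prevalence(cm, 10) == 0.0

    def test_total_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            predicted_prevalence(ConfusionMatrix(tp=1, fp=1, fn=1, tn=1), 10)


class TestCohensKappa:
    def test_identical_sequences(self):
        assert cohens_kappa(["+", "-", "+", "-"], ["+", "-", "+", "-"]) == 1.0

    def test_agreement_no_better_than_chance(self):
        # observed agreement 0.5 equals expected agreement 0.5
        assert cohens_kappa(list("++--"), list("+-+-")) == pytest.approx(0.0)

    def test_degenerate_single_category_is_undefined(self):
        assert math.isnan(cohens_kappa(["+", "+"], ["+", "+"]))

    def test_length_mismatch(self):
        with pytest.raises(EvaluationError):
            cohens_kappa(["+"], ["+", "-"])

    def test_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        a = rng.choice(["definite", "possible", "none"], size=200).tolist()
        b = [x if rng.random() < 0.7 else rng.choice(["definite", "possible", "none"]) for x in a]
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


class TestBuildConfusion:
    def _cohort(self):
        labels = ["definite_copd", "definite_copd", "possible_copd", "no_mention", "copd_ruled_out"]
        return [make_chart(patient_id=f"P{i}", label=lab) for i, lab in enumerate(labels)]

    def test_exhaustive_count(self):
        charts = self._cohort()
        preds = {"P0": True, "P1": True, "P2": False, "P3": False, "P4": False}
        cm = build_confusion(preds, charts)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 0, 0, 3)

    def test_possible_copd_counts_as_reference_negative(self):
        charts = self._cohort()
        preds = {"P0": True, "P1": True, "P2": True, "P3": False, "P4": False}
        cm = build_confusion(preds, charts)
        assert cm.fp == 1 and cm.tn == 2

    def test_exclude_possible_mode_drops_those_charts(self):
        charts = self._cohort()
        preds = {"P0": True, "P1": True, "P2": True, "P3": False, "P4": False}
        cm = build_confusion(preds, charts, exclude_possible=True)
        assert cm.n == 4 and cm.fp == 0

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(EvaluationError):
            build_confusion({}, [])

    def test_missing_label_is_an_error(self):
        charts = [make_chart(patient_id="P0")]
        with pytest.raises(EvaluationError, match="reference_label"):
            build_confusion({"P0": True}, charts)

    def test_id_mismatch_is_an_error(self):
        charts = [make_chart(patient_id="P0", label="no_mention")]
        with pytest.raises(EvaluationError, match="mismatch"):
            build_confusion({"P1": True}, charts)


class TestBuildReport:
    def test_catalog_report_shape_and_consistency(self, small_cohort, lexicon):
        report = build_report(small_cohort, catalog_algorithms(), lexicon)
        assert len(report.rows) == 12
        for row in report.rows:
            # recomputing every metric from the row's own counts reproduces it
            again = row_from_confusion(row.algorithm_id, row.cm)
            for name in ("sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg", "dor"):
                assert getattr(again, name).value == getattr(row, name).value
            # DOR equals LR+/LR- within rounding when all cells positive
            if min(row.cm.tp, row.cm.fp, row.cm.fn, row.cm.tn) > 0:
                assert abs(
                    round_half_up(row.dor.value, 1)
                    - round_half_up(row.lr_pos.value / row.lr_neg.value, 1)
                ) <= 0.1

    def test_deterministic(self, small_cohort, lexicon):
        specs = [catalog_algorithms()["combo_final"]]
        r1 = build_report(small_cohort, specs, lexicon)
        r2 = build_report(small_cohort, specs, lexicon)
        assert r1 == r2


def test_round_half_up_is_half_up():
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(2.5, 0) == 3.0
    assert round_half_up(51.049, 1) == 51.0
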