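"""Diagnostic metrics, reconstruction, Fisher/RR, ROC, survival statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunomark import evaluation as ev


class TestConfusion:
    def test_perfect_and_inverted_predictions(self):
        y = [1, 0, 1, 0, 1]
        assert ev.confusion(y, y).fp == ev.confusion(y, y).fn == 0
        inv = ev.confusion([1 - v for v in y], y)
        assert inv.tp == inv.tn == 0

    def test_four_sample_enumeration(self):
        cm = ev.confusion(
            ["non-progressor", "non-progressor", "progressor", "progressor"],
            ["non-progressor", "progressor", "progressor", "non-progressor"],
        )
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ev.confusion([1, 0], [1])


class TestDiagnosticMetrics:
    def test_biomarker_column_two_decimals(self):
        got = ev.diagnostic_metrics(ev.ConfusionMatrix(33, 18, 9, 43)).rounded()
        expected = pd.Series({
            "accuracy": 0.74, "sensitivity": 0.79, "specificity": 0.70,
            "prevalence": 0.41, "fpr": 0.30, "fnr": 0.21, "ppv": 0.65,
            "npv": 0.83, "lr_plus": 2.66, "lr_minus": 0.30, "dor": 8.76,
        })
        pd.testing.assert_series_equal(got, expected)

    def test_comparator_column_two_decimals(self):
        got = ev.diagnostic_metrics(ev.ConfusionMatrix(25, 24, 14, 37)).rounded()
        expected = pd.Series({
            "accuracy": 0.62, "sensitivity": 0.64, "specificity": 0.61,
            "prevalence": 0.39, "fpr": 0.39, "fnr": 0.36, "ppv": 0.51,
            "npv": 0.73, "lr_plus": 1.63, "lr_minus": 0.59, "dor": 2.75,
        })
        pd.testing.assert_series_equal(got, expected)

    def test_empty_positive_class_flagged_not_raised(self):
        m = ev.diagnostic_metrics(ev.ConfusionMatrix(0, 0, 0, 10))
        assert math.isnan(m.sensitivity)
        assert "sensitivity" in m.undefined
        assert m.specificity == 1.0

    @given(
        tp=st.integers(0, 60), fp=st.integers(0, 60),
        fn=st.integers(0, 60), tn=st.integers(0, 60),
    )
    @settings(max_examples=200, derandomize=True)
    def test_internal_identities_hold_exactly(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = ev.diagnostic_metrics(ev.ConfusionMatrix(tp, fp, fn, tn))
        if not math.isnan(m.sensitivity):
            assert m.fnr == 1 - m.sensitivity
        if not math.isnan(m.specificity):
            assert m.fpr == 1 - m.specificity
        if not math.isnan(m.dor):
            assert m.dor == (tp * tn) / (fp * fn)
        if not (math.isnan(m.lr_plus) or math.isnan(m.lr_minus)) and m.lr_minus > 0:
            assert m.dor == pytest.approx(m.lr_plus / m.lr_minus, rel=1e-12)


class TestReconstructConfusion:
    def test_study_sized_reconstruction_is_unique(self):
        cm = ev.reconstruct_confusion(103, 0.41, 0.79, 0.70)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (33, 18, 9, 43)

    def test_comparator_reconstruction(self):
        cm = ev.reconstruct_confusion(100, 0.39, 0.64, 0.61)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (25, 24, 14, 37)

    def test_perfect_classifier_toy(self):
        cm = ev.reconstruct_confusion(10, 0.50, 1.00, 1.00)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (5, 0, 0, 5)

    def test_no_solution_is_explicit(self):
        with pytest.raises(ValueError, match="no confusion matrix"):
            ev.reconstruct_confusion(10, 0.41, 0.79, 0.70)

    def test_ambiguity_is_explicit(self):
        # n=250, prevalence 0.50: several integer splits round identically
        with pytest.raises(ValueError, match="ambiguous"):
            ev.reconstruct_confusion(250, 0.50, 0.50, 0.50)

    def test_round_trip_never_returns_a_different_matrix(self):
        """Random matrices: reconstruction from 2-dp metrics either recovers
        the original exactly or reports ambiguity — never a wrong unique answer."""
        rng = np.random.default_rng(17)
        recovered = 0
        for _ in range(300):
            n = int(rng.integers(4, 201))
            pos = int(rng.integers(1, n))
            tp = int(rng.integers(0, pos + 1))
            tn = int(rng.integers(0, n - pos + 1))
            cm = ev.ConfusionMatrix(tp, n - pos - tn, pos - tp, tn)
            m = ev.diagnostic_metrics(cm)
            try:
                back = ev.reconstruct_confusion(
                    n,
                    ev.round_half_up(m.prevalence, 2),
                    ev.round_half_up(m.sensitivity, 2),
                    ev.round_half_up(m.specificity, 2),
                )
            except ValueError as exc:
                assert "ambiguous" in str(exc)
                continue
            assert back == cm
            recovered += 1
        assert recovered > 100  # most draws are unambiguous


class TestRates:
    def test_dcr_display_values(self):
        rates = ev.group_rate({"non_prog": [1] * 33 + [0] * 18, "prog": [1] * 9 + [0] * 43})
        assert ev.round_half_up(100 * rates.loc["non_prog", "rate"]) == 65
        assert ev.round_half_up(100 * rates.loc["prog", "rate"]) == 17

    def test_zero_successes(self):
        rates = ev.group_rate({"g": [0, 0, 0]})
        assert rates.loc["g", "rate"] == 0.0

    def test_empty_group_flagged(self):
        rates = ev.group_rate({"g": [], "h": [1]})
        assert rates.loc["g", "empty"]
        assert math.isnan(rates.loc["g", "rate"])


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[3, 1], [1, 3]], 0.4857),
            ([[5, 0], [0, 5]], 2 / 252),
            ([[4, 6], [4, 6]], 1.0),
        ],
    )
    def test_known_values(self, table, expected):
        assert ev.fisher_2x2(table) == pytest.approx(expected, abs=1e-4)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ev.fisher_2x2([[1, -2], [3, 4]])


class TestRelativeRisk:
    def test_study_arithmetic(self):
        rr, _ = ev.relative_risk(43, 52, 18, 51)
        assert rr == pytest.approx(2.3429, abs=1e-4)
        assert ev.round_half_up(rr, 2) == 2.34

    def test_identical_rates_unity(self):
        rr, (lo, hi) = ev.relative_risk(5, 10, 10, 20)
        assert rr == 1.0
        assert lo < 1.0 < hi

    def test_simple_arithmetic(self):
        assert ev.relative_risk(10, 10, 5, 10)[0] == 2.0

    def test_zero_reference_rate_flagged_infinite(self):
        rr, _ = ev.relative_risk(3, 10, 0, 10)
        assert math.isinf(rr)


def _auc_pairs(scores, labels):
    """Brute-force pair-counting oracle with half-credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_interleaved_example(self):
        auc, _ = ev.roc_auc([10, 20, 30, 40], [0, 1, 0, 1])
        assert auc == 0.75

    def test_perfect_separation_and_all_ties(self):
        assert ev.roc_auc([1, 2, 3, 4], [0, 0, 1, 1])[0] == 1.0
        assert ev.roc_auc([5, 5, 5, 5], [0, 0, 1, 1])[0] == 0.5

    def test_label_inversion_antisymmetry(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        a, _ = ev.roc_auc(s, y)
        b, _ = ev.roc_auc(s, 1 - y)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_matches_pair_count_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 8, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc, _ = ev.roc_auc(scores, labels)
            assert auc == pytest.approx(_auc_pairs(scores, labels), abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        _, curve = ev.roc_auc(s, y)
        assert curve.iloc[0][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert curve.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]
        assert curve["fpr"].is_monotonic_increasing
        assert curve["tpr"].is_monotonic_increasing

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_auc([1, 2], [1, 1])


class TestQuartileDcr:
    def test_constant_outcomes_equal_pooled_rate(self):
        q = [1] * 5 + [2] * 5 + [3] * 5 + [4] * 5
        res = ev.quartile_dcr(q, [1] * 20)
        assert (res["rate"] == res["pooled_rate"]).all()
        assert (res["fisher_p"] == 1.0).all()

    def test_enriched_quartile_is_significant(self):
        q = [4] * 25 + [1] * 78
        y = [1] * 16 + [0] * 9 + [1] * 26 + [0] * 52
        res = ev.quartile_dcr(q, y)
        assert res.loc[4, "fisher_p"] < 0.05
        assert res.loc[4, "stars"] != ""


class TestComparePredictors:
    def test_identical_predictors_fully_concordant(self):
        y = [1, 0, 1, 0]
        p = [1, 1, 0, 0]
        rep = ev.compare_predictors(p, p, y)
        assert rep["concordant"] == 4
        assert rep["discordant_errors_a"] == {"false_positives": 0, "false_negatives": 0}

    def test_discordant_errors_partition_discordant_samples(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 100)
        a = rng.integers(0, 2, 100)
        b = rng.integers(0, 2, 100)
        rep = ev.compare_predictors(a, b, y)
        err = rep["discordant_errors_a"], rep["discordant_errors_b"]
        total_errors = sum(e["false_positives"] + e["false_negatives"] for e in err)
        assert total_errors == rep["discordant"]
        assert rep["concordant"] + rep["discordant"] == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.compare_predictors([1, 0], [1], [1, 0])


class TestSurvival:
    def test_identical_groups_null_logrank(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 1, 1, 1, 1, 1]
        g = ["a"] * 4 + ["b"] * 4
        fit = ev.km_logrank(t, e, g)
        assert fit.statistic == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value == pytest.approx(1.0, abs=1e-12)

    def test_km_medians_by_hand(self):
        fit = ev.km_logrank([1, 2, 3, 4, 5, 6], [1] * 6, ["a"] * 3 + ["b"] * 3)
        assert fit.medians["a"] == 2.0
        assert fit.medians["b"] == 5.0

    def test_no_events_curve_stays_at_one(self):
        fit = ev.km_logrank([5, 6, 7, 8], [0, 0, 0, 0], ["a", "a", "b", "b"])
        for curve in fit.curves.values():
            assert (curve["survival"] == 1.0).all()
        assert all(math.isinf(m) or math.isnan(m) for m in fit.medians.values())

    def test_km_curves_non_increasing_from_one(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        fit = ev.km_logrank(t, e, rng.integers(0, 2, 60))
        for curve in fit.curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] == 1.0
            assert (np.diff(surv) <= 1e-12).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ev.km_logrank([1, 2], [1, 1], ["a", "a"])


def _cox_partial_loglik(beta, times, events, x):
    """Brute-force partial likelihood oracle (no ties in the toy data)."""
    order = np.argsort(times)
    t, e, xs = np.asarray(times)[order], np.asarray(events)[order], np.asarray(x)[order]
    ll = 0.0
    for i in range(len(t)):
        if e[i] == 1:
            risk = xs[i:]
            ll += beta * xs[i] - math.log(np.sum(np.exp(beta * risk)))
    return ll


class TestCoxPh:
    def test_toy_fit_matches_grid_maximizer(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 1, 1, 1, 1]
        x = [0.5, -0.2, 1.0, -1.0, 0.3]
        res = ev.cox_ph(times, events, pd.DataFrame({"x": x}))
        grid = np.arange(-4, 4, 1e-4)
        lls = [_cox_partial_loglik(b, times, events, x) for b in grid]
        assert res.loc["x", "coef"] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(11)
        n = 1000
        t = rng.exponential(10, n)
        g = rng.integers(0, 2, n)
        res = ev.cox_ph(t, np.ones(n, dtype=int), pd.DataFrame({"g": g}))
        assert 0.85 <= res.loc["g", "hr"] <= 1.18

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(13)
        n = 500
        g = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
        t = np.where(g == 1, rng.exponential(0.5, n), rng.exponential(1.0, n))
        res = ev.cox_ph(t, np.ones(n, dtype=int), pd.DataFrame({"g": g}))
        assert 1.7 <= res.loc["g", "hr"] <= 2.3

    def test_constant_covariate_named_in_error(self):
        with pytest.raises(ValueError, match="flat"):
            ev.cox_ph([1, 2, 3], [1, 1, 1], pd.DataFrame({"flat": [1, 1, 1]}))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            ev.cox_ph([1, 2], [0, 0], pd.DataFrame({"x": [0.1, 0.9]}))
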