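"""Cohort splitting, logistic diagnostic model, confusion metrics, AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methdx as m
from methdx.diagnostic import ConfusionMatrix, roc_points
from oracles import auc_by_pairs


class TestSplitCohort:
    @pytest.mark.parametrize("n, expected", [(100, (70, 30)), (146, (102, 44))])
    def test_seven_three_split_sizes(self, n, expected):
        train, val = m.split_cohort([f"s{i}" for i in range(n)], 0.7, seed=1)
        assert (len(train), len(val)) == expected

    def test_disjoint_and_exhaustive(self):
        samples = [f"s{i}" for i in range(57)]
        train, val = m.split_cohort(samples, 0.7, seed=3)
        assert set(train) | set(val) == set(samples)
        assert set(train) & set(val) == set()

    def test_full_ratio_leaves_empty_validation(self):
        train, val = m.split_cohort(["a", "b", "c"], 1.0, seed=0)
        assert val == [] and len(train) == 3

    def test_seeded_determinism_and_variation(self):
        samples = [f"s{i}" for i in range(50)]
        assert m.split_cohort(samples, 0.7, 5) == m.split_cohort(samples, 0.7, 5)
        assert m.split_cohort(samples, 0.7, 5) != m.split_cohort(samples, 0.7, 6)


def _null_model(n=400, seed=3):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    matrix = pd.DataFrame([rng.random(n)], index=["chr1:100"], columns=samples)
    labels = pd.Series(np.where(np.arange(n) < n // 2, "malignant", "benign"),
                       index=samples)
    return matrix, labels


class TestFitModel:
    def test_null_marker_coefficient_near_zero(self):
        matrix, labels = _null_model()
        model = m.DiagnosticModel(matrix, labels, ["chr1:100"])
        res = model.fit()
        assert abs(res.params["chr1:100"]) < 0.3
        assert abs(res.params["intercept"]) < 0.2

    def test_parameter_recovery_from_known_model(self):
        """Coefficients of a generating logistic model are recovered
        within 10% at large n."""
        rng = np.random.default_rng(5)
        n = 5000
        samples = [f"s{i}" for i in range(n)]
        x1, x2 = rng.random(n), rng.random(n)
        true = {"intercept": -1.0, "chr1:100": 2.5, "chr1:200": -1.8}
        eta = true["intercept"] + true["chr1:100"] * x1 + true["chr1:200"] * x2
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        matrix = pd.DataFrame([x1, x2], index=["chr1:100", "chr1:200"], columns=samples)
        labels = pd.Series(np.where(y, "malignant", "benign"), index=samples)
        res = m.DiagnosticModel(matrix, labels, ["chr1:100", "chr1:200"]).fit()
        for term, val in true.items():
            assert res.params[term] == pytest.approx(val, rel=0.10)

    def test_separation_triggers_ridge_fallback(self):
        n = 40
        samples = [f"s{i}" for i in range(n)]
        x = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        matrix = pd.DataFrame([x], index=["chr1:100"], columns=samples)
        labels = pd.Series(np.where(x > 0.5, "malignant", "benign"), index=samples)
        res = m.DiagnosticModel(matrix, labels, ["chr1:100"]).fit()
        assert res.ridge_used and res.warning is not None
        scores = res.predict()
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_missing_marker_rejected(self):
        matrix, labels = _null_model()
        with pytest.raises(ValueError):
            m.DiagnosticModel(matrix, labels, ["chrX:1"])

    def test_summary_mentions_terms(self):
        matrix, labels = _null_model()
        res = m.DiagnosticModel(matrix, labels, ["chr1:100"]).fit()
        assert "chr1:100" in res.summary() and "intercept" in res.summary()


class TestPredict:
    def _fixed_results(self, params):
        matrix, labels = _null_model(n=20, seed=1)
        res = m.DiagnosticModel(matrix, labels, ["chr1:100"]).fit()
        res.params = pd.Series(params)
        return res

    def test_zero_model_scores_half(self):
        res = self._fixed_results({"intercept": 0.0, "chr1:100": 0.0})
        assert np.allclose(res.predict(), 0.5)

    def test_unit_logit(self):
        matrix = pd.DataFrame([[1.0]], index=["chr1:100"], columns=["s"])
        res = self._fixed_results({"intercept": 0.0, "chr1:100": 1.0})
        score = res.predict(matrix, None, samples=["s"])
        assert score["s"] == pytest.approx(0.7311, abs=1e-4)

    def test_monotone_in_positive_marker(self):
        res = self._fixed_results({"intercept": -0.3, "chr1:100": 2.0})
        grid = np.linspace(0, 1, 11)
        matrix = pd.DataFrame([grid], index=["chr1:100"],
                              columns=[f"g{i}" for i in range(11)])
        scores = res.predict(matrix, None, samples=list(matrix.columns))
        assert (np.diff(scores.to_numpy()) > 0).all()


class TestClassify:
    def test_basic_tally(self):
        scores = pd.Series({"a": 0.6, "b": 0.4})
        labels = pd.Series({"a": "malignant", "b": "benign"})
        cm = m.classify(scores, labels)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)

    def test_threshold_tie_is_positive(self):
        scores = pd.Series({"a": 0.5})
        labels = pd.Series({"a": "malignant"})
        assert m.classify(scores, labels, threshold=0.5).tp == 1

    def test_all_positive_scores(self):
        scores = pd.Series({"a": 1.0, "b": 1.0})
        labels = pd.Series({"a": "malignant", "b": "benign"})
        cm = m.classify(scores, labels)
        assert cm.fn == 0 and cm.tn == 0

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            m.classify(pd.Series({"a": 0.5}), pd.Series({"b": "benign"}))


class TestEvaluateConfusion:
    @pytest.mark.parametrize("cm, sens, spec, ppv, npv, acc", [
        (ConfusionMatrix(tp=36, fn=4, fp=1, tn=29), 90, 97, 0.973, 0.879, 0.929),
        (ConfusionMatrix(tp=12, fn=1, fp=1, tn=16), 92, 94, 0.923, 0.941, 0.933),
        (ConfusionMatrix(tp=61, fn=1, fp=0, tn=40), 98, 100, 1.000, 0.976, 0.990),
        (ConfusionMatrix(tp=22, fn=5, fp=7, tn=10), 81, 59, 0.759, 0.667, 0.727),
    ])
    def test_report_rounding_convention(self, cm, sens, spec, ppv, npv, acc):
        disp = m.evaluate_confusion(cm).display()
        assert disp["sensitivity_pct"] == sens
        assert disp["specificity_pct"] == spec
        assert disp["ppv"] == pytest.approx(ppv, abs=5e-4)
        assert disp["npv"] == pytest.approx(npv, abs=5e-4)
        assert disp["accuracy"] == pytest.approx(acc, abs=5e-4)

    def test_perfect_two_by_two(self):
        metrics = m.evaluate_confusion(ConfusionMatrix(tp=1, fn=0, fp=0, tn=1))
        assert metrics.sensitivity == metrics.specificity == 1.0
        assert metrics.ppv == metrics.npv == metrics.accuracy == 1.0

    def test_undefined_metrics_are_nan(self):
        metrics = m.evaluate_confusion(ConfusionMatrix(tp=0, fn=0, fp=1, tn=1))
        assert np.isnan(metrics.sensitivity) and not np.isnan(metrics.npv)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            m.evaluate_confusion(ConfusionMatrix(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = pd.Series({"a": 0.9, "b": 0.8, "c": 0.2, "d": 0.1})
        labels = pd.Series({"a": "malignant", "b": "malignant",
                            "c": "benign", "d": "benign"})
        assert m.roc_auc(scores, labels) == 1.0

    def test_pair_enumeration_example(self):
        scores = pd.Series({"a": 0.9, "b": 0.8, "c": 0.7, "d": 0.85})
        labels = pd.Series({"a": "malignant", "b": "malignant",
                            "c": "benign", "d": "benign"})
        assert m.roc_auc(scores, labels) == pytest.approx(0.75)

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(6)
        n = 2000
        scores = pd.Series(rng.random(n), index=[f"s{i}" for i in range(n)])
        labels = pd.Series(rng.permutation(np.r_[["malignant"] * (n // 2),
                                                 ["benign"] * (n // 2)]),
                           index=scores.index)
        assert abs(m.roc_auc(scores, labels) - 0.5) < 0.03

    def test_single_class_rejected(self):
        scores = pd.Series({"a": 0.5, "b": 0.6})
        labels = pd.Series({"a": "malignant", "b": "malignant"})
        with pytest.raises(ValueError):
            m.roc_auc(scores, labels)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_midrank_auc_equals_pair_enumeration(self, data):
        """Midrank AUC equals brute-force case-control pair counting,
        including ties, on all inputs up to 50 samples."""
        n1 = data.draw(st.integers(1, 25))
        n0 = data.draw(st.integers(1, 25))
        vals = data.draw(st.lists(st.integers(0, 10), min_size=n1 + n0,
                                  max_size=n1 + n0))
        scores = pd.Series(np.asarray(vals, dtype=float) / 10,
                           index=[f"s{i}" for i in range(n1 + n0)])
        lab = ["malignant"] * n1 + ["benign"] * n0
        labels = pd.Series(lab, index=scores.index)
        assert m.roc_auc(scores, labels) == pytest.approx(
            auc_by_pairs(scores.to_numpy(), lab))

    def test_trapezoid_area_matches_midrank(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.random(60), index=[f"s{i}" for i in range(60)])
        labels = pd.Series(np.where(rng.random(60) < 0.5, "malignant", "benign"),
                           index=scores.index)
        pts = roc_points(scores, labels)
        area = np.trapezoid(pts["tpr"], pts["fpr"])
        assert area == pytest.approx(m.roc_auc(scores, labels))


class TestEndToEndConsistency:
    def test_confusion_metrics_internally_consistent(self, small_matrix):
        matrix, metadata, truth = small_matrix
        res = m.DiagnosticModel.from_cohort(matrix, metadata, truth.planted_sites).fit()
        ev = res.evaluate()
        cm = ev["confusion"]
        assert ev["metrics"].sensitivity == pytest.approx(cm.tp / (cm.tp + cm.fn))
        assert ev["metrics"].accuracy == pytest.approx((cm.tp + cm.tn) / cm.total)
        assert cm.total == len(metadata)

    def test_model_json_roundtrip_fields(self, small_matrix, tmp_path):
        matrix, metadata, truth = small_matrix
        res = m.DiagnosticModel.from_cohort(matrix, metadata, truth.planted_sites).fit()
        payload = res.to_json(tmp_path / "model.json")
        assert set(payload["markers"]) == set(truth.planted_sites)
        assert set(payload["params"]) == set(res.params.index)
        assert (tmp_path / "model.json").exists()
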