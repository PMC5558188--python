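"""The six performance measures, cross-validation, and the rule /
reference / hybrid evaluations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm

from prdis.evaluate import (
    CvPlan,
    compute_metrics,
    confusion_counts,
    cross_validate,
    evaluate_coincidence_rule,
    evaluate_hybrid,
    evaluate_reference_predictor,
)
from prdis.io_formats import MISSING, VariantRecord
from prdis.learn import TrainingConfig, smote_oversample, train_on_records
from prdis.partition import PredictorSpec, apply_coincidence_rule


class TestComputeMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(5, 5, 0, 0)
        assert r.mcc == pytest.approx(1.0)
        assert r.accuracy == pytest.approx(1.0)

    def test_hand_derived_table(self):
        r = compute_metrics(3, 4, 1, 2)
        assert r.accuracy == pytest.approx(0.7)
        assert r.mcc == pytest.approx(
            (3 * 4 - 1 * 2) / math.sqrt(5 * 5 * 4 * 6)
        )
        assert r.mcc == pytest.approx(0.4082, abs=1e-4)
        assert r.sensitivity == pytest.approx(0.6)
        assert r.specificity == pytest.approx(0.8)
        assert r.ppv == pytest.approx(0.75)
        assert r.npv == pytest.approx(4 / 6)

    def test_degenerate_all_positive_caller(self):
        r = compute_metrics(7, 0, 7, 0)
        assert r.sensitivity == 1.0
        assert r.specificity == 0.0
        assert r.mcc is None  # undefined, not coerced to 0
        assert r.npv is None

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 0, 0)
        with pytest.raises(ValueError):
            compute_metrics(-1, 1, 1, 1)

    @settings(derandomize=True, max_examples=1000)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_agrees_with_per_variant_tally(self, counts):
        """Formula output matches a brute-force tally (via sklearn) on the
        unrolled prediction vectors, over random confusion tables."""
        TP, TN, FP, FN = counts
        if TP + TN + FP + FN == 0:
            return
        y_true = [1] * TP + [0] * TN + [0] * FP + [1] * FN
        y_pred = [1] * TP + [0] * TN + [1] * FP + [0] * FN
        assert confusion_counts(y_true, y_pred) == (TP, TN, FP, FN)
        r = compute_metrics(TP, TN, FP, FN)
        assert r.accuracy == pytest.approx(skm.accuracy_score(y_true, y_pred))
        denom = (TP + FN) * (TN + FP) * (TP + FP) * (TN + FN)
        if denom > 0:
            assert r.mcc == pytest.approx(
                skm.matthews_corrcoef(y_true, y_pred), abs=1e-12
            )
        if TP + FN > 0:
            assert r.sensitivity == pytest.approx(
                skm.recall_score(y_true, y_pred, zero_division=np.nan)
            )

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_mcc_invariant_under_class_swap(self, counts):
        TP, TN, FP, FN = counts
        denom = (TP + FN) * (TN + FP) * (TP + FP) * (TN + FN)
        if denom == 0:
            return
        assert compute_metrics(TP, TN, FP, FN).mcc == pytest.approx(
            compute_metrics(TN, TP, FN, FP).mcc
        )

    def test_balanced_random_caller_has_near_zero_mcc(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 4000)
        y_pred = rng.integers(0, 2, 4000)
        r = compute_metrics(*confusion_counts(y_true, y_pred))
        assert abs(r.mcc) < 0.05


def prdis_subset(panel, combination):
    _, records, _, registry = panel
    result = apply_coincidence_rule(records, combination, registry)
    return [records[i] for i in sorted(result.prdis)]


class TestCrossValidate:
    def test_folds_partition_data_and_test_folds_keep_class_counts(self):
        """Each replica's test folds cover the data exactly once, and the
        SMOTE step never alters a held-out fold."""
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(1)
        X = rng.random((60, 3))
        y = np.array([0] * 40 + [1] * 20)
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = []
        for train_idx, test_idx in splitter.split(X, y):
            X_te_before = X[test_idx].tobytes()
            y_te_before = y[test_idx].tobytes()
            smote_oversample(X[train_idx], y[train_idx], k=3, seed=0)
            assert X[test_idx].tobytes() == X_te_before
            assert y[test_idx].tobytes() == y_te_before
            seen.extend(test_idx.tolist())
        assert sorted(seen) == list(range(60))

    def test_mean_mcc_bounded_by_replica_extremes(self, default_panel):
        records = prdis_subset(default_panel, ("SIFT", "PolyPhen2"))
        cfg = TrainingConfig(epochs=60)
        plan = CvPlan(n_replicas=3, seeds=[0, 1, 2])
        mean_report, replicas = cross_validate(
            records, ("SIFT", "PolyPhen2"), cfg, plan
        )
        mccs = [r.mcc for r in replicas]
        assert min(mccs) - 1e-12 <= mean_report.mcc <= max(mccs) + 1e-12
        assert len(replicas) == 3

    def test_single_class_input_rejected(self):
        recs = [
            VariantRecord("P1", "A", i + 1, "V", label="neutral",
                          predictor_outputs={"A": 0.1, "B": 0.2})
            for i in range(20)
        ]
        with pytest.raises(ValueError):
            cross_validate(recs, ("A", "B"), TrainingConfig(epochs=5),
                           CvPlan(n_replicas=1, seeds=[0]))


class TestCoincidenceRuleEvaluation:
    def test_always_right_predictors_give_mcc_one(self, two_predictor_registry):
        records = [
            VariantRecord("P1", "A", i + 1, "V",
                          label="pathogenic" if i % 2 else "neutral",
                          predictor_outputs={"A": 0.9 if i % 2 else 0.1,
                                             "B": 0.8 if i % 2 else 0.2})
            for i in range(10)
        ]
        part = apply_coincidence_rule(records, ("A", "B"),
                                      two_predictor_registry)
        report = evaluate_coincidence_rule(records, part)
        assert report.mcc == pytest.approx(1.0)
        assert report.coverage == 1.0

    def test_eight_variant_manual_tally(self, eight_variant_fixture,
                                        two_predictor_registry):
        part = apply_coincidence_rule(eight_variant_fixture, ("A", "B"),
                                      two_predictor_registry)
        report = evaluate_coincidence_rule(eight_variant_fixture, part)
        # agree members: v0 TP, v1 FN, v5 TN, v6 FP (see fixture docstring)
        assert (report.TP, report.TN, report.FP, report.FN) == (1, 1, 1, 1)
        assert report.coverage == pytest.approx(4 / 8)

    def test_empty_agree_set_flagged_undefined(self, two_predictor_registry):
        records = [
            VariantRecord("P1", "A", 1, "V", label="neutral",
                          predictor_outputs={"A": 0.9, "B": MISSING})
        ]
        part = apply_coincidence_rule(records, ("A", "B"),
                                      two_predictor_registry)
        report = evaluate_coincidence_rule(records, part)
        assert report.mcc is None and report.accuracy is None


class TestReferenceEvaluation:
    def test_manual_tally_and_coverage(self, eight_variant_fixture):
        spec = PredictorSpec("A", threshold=0.5)
        report = evaluate_reference_predictor(eight_variant_fixture, spec)
        # A outputs for 7 of 8; calls: v0 TP, v1 FN, v2 TP, v3 TP,
        # v4 TN, v5 TN, v6 FP
        assert (report.TP, report.TN, report.FP, report.FN) == (3, 2, 1, 1)
        assert report.coverage == pytest.approx(7 / 8)

    def test_predictor_with_no_outputs(self):
        records = [
            VariantRecord("P1", "A", 1, "V", label="neutral",
                          predictor_outputs={"A": MISSING})
        ]
        report = evaluate_reference_predictor(
            records, PredictorSpec("A", threshold=0.5)
        )
        assert report.coverage == 0.0
        assert report.mcc is None


class TestHybridEvaluation:
    def build_parts(self, panel):
        spec, records, _, registry = panel
        combo = ("SIFT", "PolyPhen2")
        part = apply_coincidence_rule(records, combo, registry)
        prdis_records = [records[i] for i in sorted(part.prdis)]
        model = train_on_records(
            prdis_records, combo, TrainingConfig(epochs=60)
        )
        return records, part, prdis_records, model

    def test_pooled_counts_equal_sum_of_parts(self, default_panel):
        records, part, prdis_records, model = self.build_parts(default_panel)
        hybrid = evaluate_hybrid(records, part, model)
        agree = evaluate_coincidence_rule(records, part)
        _, calls = model.predict_records(prdis_records)
        y_true = [1 if r.label == "pathogenic" else 0 for r in prdis_records]
        y_pred = [1 if c == "pathogenic" else 0 for c in calls]
        tp, tn, fp, fn = confusion_counts(y_true, y_pred)
        assert hybrid.TP == agree.TP + tp
        assert hybrid.TN == agree.TN + tn
        assert hybrid.FP == agree.FP + fp
        assert hybrid.FN == agree.FN + fn
        # pooled MCC equals direct recomputation from the pooled counts
        direct = compute_metrics(hybrid.TP, hybrid.TN, hybrid.FP, hybrid.FN)
        assert hybrid.mcc == pytest.approx(direct.mcc)

    def test_coverage_is_agree_plus_prdis_over_initial(self, default_panel):
        records, part, _, model = self.build_parts(default_panel)
        hybrid = evaluate_hybrid(records, part, model)
        assert hybrid.coverage == pytest.approx(
            (len(part.agree) + len(part.prdis)) / len(records)
        )

    def test_combination_mismatch_rejected(self, default_panel):
        records, part, _, model = self.build_parts(default_panel)
        bad = apply_coincidence_rule(records, ("SIFT", "CADD"),
                                     default_panel[3])
        with pytest.raises(ValueError):
            evaluate_hybrid(records, bad, model)
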