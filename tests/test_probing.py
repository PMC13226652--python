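"""Probe heads, weighted BCE, fold assignment, and patient-level metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magcardia import nn
from magcardia.probing import (ProbeHead, aggregate_patient,
                               audit_fold_assignment, class_weights,
                               compute_metrics, fold_ci,
                               patient_labels_from_segments,
                               permute_patient_labels,
                               stratified_patient_folds, swish,
                               weighted_bce_with_logits)
from magcardia.preprocess import Segment


def brute_force_auc(scores, labels):
    """All-pairs counting with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _seg(pid, label, idx=0):
    return Segment(signal=np.zeros((64, 5000), np.float32), fs=500,
                   patient_id=pid, segment_index=idx,
                   valid_channels=np.ones(64, bool), labels={"lcx": label})


class TestProbeHead:
    def test_swish_closed_form_values(self):
        assert swish(np.array([0.0]))[0] == 0.0
        assert swish(np.array([1.0]))[0] == pytest.approx(0.73106, abs=1e-5)

    def test_inference_score_lies_in_unit_interval(self, rng):
        head = ProbeHead(16, np.random.default_rng(0))
        p = head.predict(rng.standard_normal((10, 16)).astype(np.float32))
        assert np.all((p > 0) & (p < 1))

    def test_dropout_off_at_inference(self, rng):
        head = ProbeHead(16, np.random.default_rng(0))
        e = rng.standard_normal((5, 16)).astype(np.float32)
        assert np.array_equal(head.predict(e), head.predict(e))


class TestWeightedBce:
    def test_closed_form_toy_batch(self):
        # p = 0.5 both, y = (1, 0), w = (2, 1) -> (2 ln2 + ln2)/3 = ln 2
        logits = np.zeros(2)
        loss = weighted_bce_with_logits(logits, np.array([1.0, 0.0]),
                                        np.array([2.0, 1.0]))
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_doubling_a_weight_doubles_its_contribution(self, rng):
        logits = rng.standard_normal(6)
        y = np.array([1, 0, 1, 0, 1, 0], float)
        per_sample = (np.log1p(np.exp(-np.abs(logits)))
                      + np.maximum(logits, 0) - logits * y)
        w = np.ones(6)
        w2 = w.copy()
        w2[3] = 2.0
        num1 = weighted_bce_with_logits(logits, y, w) * w.sum()
        num2 = weighted_bce_with_logits(logits, y, w2) * w2.sum()
        assert num2 - num1 == pytest.approx(per_sample[3], rel=1e-9)

    def test_class_weights_inverse_frequency(self):
        w = class_weights(np.array([1, 1, 1, 0]))
        assert np.allclose(w, [2 / 3, 2 / 3, 2 / 3, 2.0])

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.standard_normal(4)
        y = np.array([1, 0, 0, 1], float)
        w = np.array([1.0, 2.0, 1.0, 3.0])
        _, g = weighted_bce_with_logits(logits, y, w, return_grad=True)
        eps = 1e-6
        for i in range(4):
            lp = logits.copy(); lp[i] += eps
            lm = logits.copy(); lm[i] -= eps
            num = (weighted_bce_with_logits(lp, y, w)
                   - weighted_bce_with_logits(lm, y, w)) / (2 * eps)
            assert g[i] == pytest.approx(num, abs=1e-6)


class TestFolds:
    def test_exact_divisibility_40_patients(self):
        labels = {f"p{i}": int(i < 20) for i in range(40)}
        folds = stratified_patient_folds(labels, k=5, seed=0)
        for f in range(5):
            members = [p for p, v in folds.items() if v == f]
            assert len(members) == 8
            assert sum(labels[p] for p in members) == 4

    def test_fold_sizes_differ_by_at_most_one(self):
        labels = {f"p{i}": int(i % 2) for i in range(41)}
        folds = stratified_patient_folds(labels, k=5, seed=1)
        sizes = [list(folds.values()).count(f) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_train_and_validation_patients_disjoint_in_every_fold(self):
        labels = {f"p{i}": int(i < 10) for i in range(25)}
        folds = stratified_patient_folds(labels, k=5, seed=2)
        for f in range(5):
            val = {p for p, v in folds.items() if v == f}
            train = {p for p, v in folds.items() if v != f}
            assert not val & train
            assert val | train == set(labels)

    def test_deterministic_given_seed(self):
        labels = {f"p{i}": int(i < 10) for i in range(20)}
        assert (stratified_patient_folds(labels, 5, seed=3)
                == stratified_patient_folds(labels, 5, seed=3))

    def test_too_few_patients_per_class_rejected(self):
        labels = {"a": 1, "b": 0, "c": 0, "d": 0, "e": 0, "f": 0}
        with pytest.raises(ValueError, match="fewer than"):
            stratified_patient_folds(labels, k=5)

    def test_audit_rejects_leaky_assignment(self):
        segs = [_seg("pA", 1, 0), _seg("pA", 1, 1), _seg("pB", 0, 0)]
        good = {"pA": 0, "pB": 1}
        audit_fold_assignment(good, segs, k=2)  # passes
        with pytest.raises(ValueError, match="no fold"):
            audit_fold_assignment({"pA": 0}, segs, k=2)
        with pytest.raises(ValueError, match="out of range"):
            audit_fold_assignment({"pA": 5, "pB": 1}, segs, k=2)


class TestAggregation:
    def test_mean_of_segment_scores(self):
        pids, scores = aggregate_patient([0.2, 0.4, 0.6], ["a", "a", "a"])
        assert pids == ["a"] and scores[0] == pytest.approx(0.4)

    def test_single_segment_passthrough(self):
        _, scores = aggregate_patient([0.9], ["a"])
        assert scores[0] == pytest.approx(0.9)

    def test_order_invariance(self):
        _, s1 = aggregate_patient([0.1, 0.9, 0.5], ["a", "b", "a"])
        _, s2 = aggregate_patient([0.5, 0.1, 0.9], ["a", "a", "b"])
        assert np.allclose(s1, s2)


class TestMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert m["auc"] == 1.0
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_pair_counting_example(self):
        # pos {0.9, 0.8}, neg {0.7, 0.85}: 3 of 4 pairs correctly ordered
        m = compute_metrics([0.9, 0.8, 0.7, 0.85], [1, 1, 0, 0])
        assert m["auc"] == pytest.approx(0.75)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 50), st.integers(0, 10**6))
    def test_rank_auc_equals_all_pairs_counting(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, int)
        labels[: n // 2] = 1
        if labels.sum() == 0 or labels.sum() == n:
            return
        scores = np.round(rng.random(n), 2)  # coarse grid -> ties occur
        m = compute_metrics(scores, labels)
        assert m["auc"] == pytest.approx(brute_force_auc(scores, labels),
                                         abs=1e-12)

    def test_label_permutation_null_centres_on_half(self):
        rng = np.random.default_rng(4)
        scores = rng.random(30)
        labels = np.array([1] * 15 + [0] * 15)
        aucs = [compute_metrics(scores, rng.permutation(labels))["auc"]
                for _ in range(1000)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0.1, 0.9], [1, 1])

    def test_fold_ci_is_symmetric_t_interval(self):
        mean, lo, hi = fold_ci([0.8, 0.9, 0.85, 0.95, 0.9])
        assert lo < mean < hi
        assert mean == pytest.approx(0.88)
        assert hi - mean == pytest.approx(mean - lo)


class TestThresholdAndCi:
    def test_youden_separates_separable_scores(self):
        from magcardia.probing import youden_threshold
        thr = youden_threshold(np.array([0.9, 0.8, 0.2, 0.1]),
                               np.array([1, 1, 0, 0]))
        assert 0.2 < thr <= 0.8

    def test_bootstrap_ci_brackets_the_point_estimate(self):
        from magcardia.probing import bootstrap_auc_ci
        rng = np.random.default_rng(0)
        labels = np.array([1] * 20 + [0] * 20)
        scores = labels * 0.5 + rng.random(40) * 0.6
        point, lo, hi = bootstrap_auc_ci(scores, labels, n_resamples=200)
        assert 0.0 <= lo <= point <= hi <= 1.0
        assert hi - lo > 0

    def test_pooled_vessel_metrics_pools_all_predictions(self):
        from magcardia.probing import FoldOutcome, ProbeResult, pooled_vessel_metrics
        def mk(task, scores, labels):
            f = FoldOutcome(0, compute_metrics(scores, labels), ["a", "b"],
                            np.array(scores), np.array(labels),
                            np.array(scores), [], None, None)
            return ProbeResult(task=task, folds=[f])
        pooled = pooled_vessel_metrics([mk("lad", [0.9, 0.1], [1, 0]),
                                        mk("lcx", [0.8, 0.3], [1, 0])])
        assert pooled["auc"] == 1.0


class TestLabelPlumbing:
    def test_patient_labels_collected_from_segments(self):
        segs = [_seg("a", 1), _seg("a", 1, 1), _seg("b", 0)]
        assert patient_labels_from_segments(segs, "lcx") == {"a": 1, "b": 0}

    def test_inconsistent_patient_labels_rejected(self):
        segs = [_seg("a", 1), _seg("a", 0, 1)]
        with pytest.raises(ValueError):
            patient_labels_from_segments(segs, "lcx")

    def test_permutation_preserves_label_counts(self):
        segs = [_seg(f"p{i}", int(i < 4), j) for i in range(10) for j in range(2)]
        perm = permute_patient_labels(segs, "lcx", seed=0)
        orig = patient_labels_from_segments(segs, "lcx")
        new = patient_labels_from_segments(perm, "lcx")
        assert sum(orig.values()) == sum(new.values())
        assert orig != new  # seed 0 actually moves at least one label
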