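"""Metric oracle equivalence, invariances, and the K-fold protocol."""

import numpy as np
import pytest

from fedsilo import (
    FederationConfig,
    ModelSpec,
    compute_metrics,
    kfold_protocol,
    measure_runtime,
)
from fedsilo.exceptions import ValidationError


# --- independent brute-force reference (explicit loops) -------------------

def brute_force_metrics(labels, scores, threshold=0.5):
    labels = list(labels)
    scores = list(scores)
    n = len(labels)
    pos = [scores[i] for i in range(n) if labels[i] == 1]
    neg = [scores[i] for i in range(n) if labels[i] == 0]

    # ROC-AUC: pairwise comparisons, ties 1/2
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    roc = wins / (len(pos) * len(neg))

    # AUC-PR: step-wise average precision over descending distinct scores
    distinct = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in distinct:
        tp = fp = 0
        for i in range(n):
            if scores[i] >= t:
                if labels[i] == 1:
                    tp += 1
                else:
                    fp += 1
        precision = tp / (tp + fp)
        recall = tp / len(pos)
        ap += (recall - prev_recall) * precision
        prev_recall = recall

    # confusion at threshold
    tp = fp = tn = fn = 0
    for i in range(n):
        pred = 1 if scores[i] >= threshold else 0
        if pred == 1 and labels[i] == 1:
            tp += 1
        elif pred == 1 and labels[i] == 0:
            fp += 1
        elif pred == 0 and labels[i] == 0:
            tn += 1
        else:
            fn += 1
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn)
    tnr = tn / (tn + fp)
    bal = (rec + tnr) / 2.0

    def fbeta(beta):
        if prec == 0.0 and rec == 0.0:
            return 0.0
        b2 = beta * beta
        denom = b2 * prec + rec
        return (1 + b2) * prec * rec / denom if denom else 0.0

    eps = 1e-15
    ll = 0.0
    for i in range(n):
        p = min(max(scores[i], eps), 1 - eps)
        ll += -(np.log(p) if labels[i] == 1 else np.log(1 - p))
    ll /= n

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn - fp * fn) / np.sqrt(denom)) if denom else 0.0

    return {"roc_auc": roc, "auc_pr": ap, "balanced_accuracy": bal,
            "precision": prec, "recall": rec, "f_half": fbeta(0.5),
            "f1": fbeta(1.0), "f2": fbeta(2.0), "log_loss": ll, "mcc": mcc}


class TestComputeMetrics:
    def test_perfect_classifier(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        r = compute_metrics(labels, scores)
        assert r.roc_auc == r.auc_pr == r.balanced_accuracy == r.mcc == 1.0

    def test_all_positive_predictor(self):
        labels = np.array([0, 1, 0, 1, 1])
        scores = np.full(5, 0.9)
        r = compute_metrics(labels, scores)
        assert r.recall == 1.0
        assert r.balanced_accuracy == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        # mix of continuous and tied scores to exercise tie handling
        scores = np.round(rng.random(n), int(rng.integers(1, 12)))
        got = compute_metrics(labels, scores).as_dict()
        want = brute_force_metrics(labels, scores)
        for name in want:
            assert got[name] == pytest.approx(want[name], abs=1e-9), name

    def test_errors(self):
        with pytest.raises(ValidationError, match="single class"):
            compute_metrics(np.ones(4), np.full(4, 0.5))
        with pytest.raises(ValidationError, match="NaN"):
            compute_metrics(np.array([0, 1]), np.array([np.nan, 0.5]))
        with pytest.raises(ValidationError, match="\\[0, 1\\]"):
            compute_metrics(np.array([0, 1]), np.array([-0.2, 0.5]))


class TestMetricInvariances:
    def test_roc_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 100)
        labels[0], labels[1] = 0, 1
        scores = rng.random(100)
        a = compute_metrics(labels, scores).roc_auc
        b = compute_metrics(labels, scores ** 3).roc_auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_threshold_preserving_transform_fixes_all_metrics(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        scores = rng.random(80)
        # monotone map fixing 0.5: piecewise power on each side
        warped = np.where(scores >= 0.5,
                          0.5 + 0.5 * ((scores - 0.5) / 0.5) ** 2,
                          0.5 - 0.5 * ((0.5 - scores) / 0.5) ** 2)
        a = compute_metrics(labels, scores).as_dict()
        b = compute_metrics(labels, warped).as_dict()
        for name in ("roc_auc", "auc_pr", "balanced_accuracy", "precision",
                     "recall", "f_half", "f1", "f2", "mcc"):
            assert a[name] == pytest.approx(b[name], abs=1e-12), name

    def test_complement_symmetry(self):
        """Swapping labels and scores -> 1-score preserves MCC and balanced
        accuracy (for thresholds symmetric about 1/2, up to the >= vs >
        boundary, avoided by keeping scores off 0.5)."""
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 90)
        labels[:2] = [0, 1]
        scores = 0.5 + 0.49 * np.sign(rng.standard_normal(90)) * rng.random(90)
        a = compute_metrics(labels, scores)
        b = compute_metrics(1 - labels, 1 - scores + 1e-12)
        assert a.mcc == pytest.approx(b.mcc, abs=1e-9)
        assert a.balanced_accuracy == pytest.approx(b.balanced_accuracy, abs=1e-9)


class TestKFoldProtocol:
    def test_study_cohort_fold_sizes(self, study_cohort, default_shift):
        ext = study_cohort      # external content irrelevant for fold sizes
        roster = [ModelSpec("central_lr", "logistic_regression", epochs=1)]
        summaries = kfold_protocol(study_cohort, ext, roster, K=6, seed=0)
        sizes = sorted(len(a["holdout"])
                       for a in summaries["central_lr"].fold_assignments)
        assert sizes == [99, 99, 100, 100, 100, 100]

    def test_fold_partition_and_leakage_guard(self, small_cohort):
        fit_batches = []
        roster = [ModelSpec("central_lr", "logistic_regression", epochs=1)]
        summaries = kfold_protocol(small_cohort, small_cohort, roster,
                                   K=4, seed=1, on_fit=fit_batches.append)
        assignments = summaries["central_lr"].fold_assignments
        all_holdouts = np.concatenate([a["holdout"] for a in assignments])
        assert sorted(all_holdouts.tolist()) == list(range(small_cohort.n_samples))
        for a, fit_idx in zip(assignments, fit_batches):
            assert np.intersect1d(fit_idx, a["holdout"]).size == 0
            assert np.intersect1d(a["val"], a["holdout"]).size == 0
            union = np.concatenate([a["fit"], a["val"], a["holdout"]])
            assert sorted(union.tolist()) == list(range(small_cohort.n_samples))

    def test_protocol_is_deterministic(self, small_cohort):
        roster = [
            ModelSpec("central_lr", "logistic_regression", epochs=2),
            ModelSpec("fedavg_lr", "logistic_regression",
                      federation=FederationConfig("logistic_regression", 2,
                                                  rounds=2)),
        ]
        a = kfold_protocol(small_cohort, small_cohort, roster, K=3, seed=5)
        b = kfold_protocol(small_cohort, small_cohort, roster, K=3, seed=5)
        for name in a:
            assert a[name].internal == b[name].internal
            assert a[name].external == b[name].external

    def test_federated_and_central_both_scored_on_both_test_sets(
            self, small_cohort):
        roster = [
            ModelSpec("central_lr", "logistic_regression", epochs=2),
            ModelSpec("fedavg_lr", "logistic_regression",
                      federation=FederationConfig("logistic_regression", 2,
                                                  rounds=2)),
        ]
        summaries = kfold_protocol(small_cohort, small_cohort, roster,
                                   K=3, seed=2)
        for s in summaries.values():
            assert len(s.internal) == 3 and len(s.external) == 3
            assert 0.0 <= s.mean("auc_pr") <= 1.0
            assert s.sd("auc_pr") >= 0.0


class TestMeasureRuntime:
    def test_positive_finite_and_cv_reported(self, small_cohort):
        spec = ModelSpec("central_lr", "logistic_regression", epochs=2)
        report = measure_runtime(spec, small_cohort, seed=0, reps=3)
        assert all(t > 0 and np.isfinite(t) for t in report.seconds)
        assert report.cv >= 0.0

    def test_federated_slower_than_central(self, small_cohort):
        central = ModelSpec("central_lr", "logistic_regression", epochs=5)
        federated = ModelSpec(
            "fedavg_lr", "logistic_regression",
            federation=FederationConfig("logistic_regression", 4, rounds=5))
        tc = measure_runtime(central, small_cohort, seed=0).mean
        tf = measure_runtime(federated, small_cohort, seed=0).mean
        assert tf > tc
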