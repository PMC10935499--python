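"""Ten-metric evaluation suite and the K-fold benchmarking protocol.

Every model — central or federated — is scored with the same ten metrics:
ROC-AUC, AUC-PR (step-wise average-precision convention), balanced
accuracy, precision, recall, F0.5/F1/F2, log loss (probabilities clipped at
1e-15), and the Matthews correlation coefficient.  Thresholded metrics cut
at score >= threshold (default 0.5).

The protocol is stratified K-fold cross-validation on the training cohort:
each fold in turn is the internal holdout; the remainder is split 80:20
(stratified) into a fit and a validation subset; preprocessing and all
model fitting see only the fit subset, validation drives best-round
selection for federated models, and every fitted model is scored on the
holdout fold (internal) and on the full external cohort.  Results are
summarized as mean +/- sd over the K folds.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    fbeta_score,
    log_loss,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort import LabeledCohort
from .config import DEFAULT_K, DEFAULT_THRESHOLD, LOG_LOSS_EPS, logger
from .exceptions import LeakageError, ValidationError
from .federation import FederationConfig, client_seed, train_federated
from .learners import (
    LearnerHyperparams,
    ModelParams,
    get_parameters,
    init_learner,
    local_fit,
    predict_scores,
)
from .preprocess import apply_standardizer, fit_standardizer
from .silos import split as split_shards

METRIC_NAMES = (
    "roc_auc", "auc_pr", "balanced_accuracy", "precision", "recall",
    "f_half", "f1", "f2", "log_loss", "mcc",
)


def auc_pr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by step-wise summation
    (average precision), the primary comparison metric."""
    return float(average_precision_score(labels, scores))


@dataclass(frozen=True)
class MetricsReport:
    roc_auc: float
    auc_pr: float
    balanced_accuracy: float
    precision: float
    recall: float
    f_half: float
    f1: float
    f2: float
    log_loss: float
    mcc: float
    threshold: float = DEFAULT_THRESHOLD

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_metrics(labels: np.ndarray, scores: np.ndarray,
                    threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValidationError("metrics undefined with a single class present")
    if np.isnan(scores).any():
        raise ValidationError("scores contain NaN")
    if scores.min() < 0 or scores.max() > 1:
        raise ValidationError("scores must lie in [0, 1]")
    preds = (scores >= threshold).astype(int)
    clipped = np.clip(scores, LOG_LOSS_EPS, 1.0 - LOG_LOSS_EPS)
    return MetricsReport(
        roc_auc=float(roc_auc_score(labels, scores)),
        auc_pr=auc_pr(labels, scores),
        balanced_accuracy=float(balanced_accuracy_score(labels, preds)),
        precision=float(precision_score(labels, preds, zero_division=0)),
        recall=float(recall_score(labels, preds, zero_division=0)),
        f_half=float(fbeta_score(labels, preds, beta=0.5, zero_division=0)),
        f1=float(fbeta_score(labels, preds, beta=1.0, zero_division=0)),
        f2=float(fbeta_score(labels, preds, beta=2.0, zero_division=0)),
        log_loss=float(log_loss(labels, clipped, labels=[0, 1])),
        mcc=float(matthews_corrcoef(labels, preds)),
        threshold=threshold,
    )


@dataclass(frozen=True)
class ModelSpec:
    """One entry of the model roster.

    ``federation`` is None for a centrally trained model (fit for ``epochs``
    passes on the whole fit split); otherwise the model is trained
    federatedly on shards of the fit split drawn with ``split_strategy``.
    """

    name: str
    learner_kind: str
    hyper: LearnerHyperparams = field(default_factory=LearnerHyperparams)
    epochs: int = 5
    federation: FederationConfig | None = None
    split_strategy: str = "uniform_stratified"


def _derive(*parts: int) -> int:
    return int(np.random.SeedSequence(tuple(parts)).generate_state(1)[0] % 2**31)


@dataclass
class CVSummary:
    model: str
    K: int
    fold_assignments: list[dict[str, np.ndarray]]
    internal: list[MetricsReport]
    external: list[MetricsReport]
    runtime_seconds: list[float] = field(default_factory=list)

    def values(self, metric: str, test_set: str = "internal") -> np.ndarray:
        reports = self.internal if test_set == "internal" else self.external
        return np.array([getattr(r, metric) for r in reports])

    def mean(self, metric: str, test_set: str = "internal") -> float:
        return float(self.values(metric, test_set).mean())

    def sd(self, metric: str, test_set: str = "internal") -> float:
        return float(self.values(metric, test_set).std(ddof=1))

    def tidy(self) -> pd.DataFrame:
        rows = []
        for test_set, reports in (("internal", self.internal), ("external", self.external)):
            for fold, rep in enumerate(reports):
                for metric, value in rep.as_dict().items():
                    rows.append({"model": self.model, "fold": fold,
                                 "test_set": test_set, "metric": metric,
                                 "value": value})
        return pd.DataFrame(rows)

    def formatted(self, test_set: str = "internal") -> dict[str, str]:
        return {m: f"{self.mean(m, test_set):.3f} ± {self.sd(m, test_set):.3f}"
                for m in METRIC_NAMES}


def _train_one(spec: ModelSpec, fit_cohort: LabeledCohort,
               validation: tuple[np.ndarray, np.ndarray],
               fold_seed: int) -> ModelParams:
    """Fit one roster entry on the fit split only."""
    if spec.federation is None:
        learner = init_learner(spec.learner_kind, fit_cohort.n_features,
                               spec.hyper, seed=client_seed(fold_seed, 0))
        local_fit(learner, fit_cohort.features, fit_cohort.labels,
                  epochs=spec.epochs)
        return get_parameters(learner)
    fed = replace(spec.federation, seed=fold_seed,
                  learner_kind=spec.learner_kind, hyper=spec.hyper)
    shardset = split_shards(fit_cohort, spec.split_strategy,
                            fed.n_clients, seed=_derive(fold_seed, 7))
    shard_datas = [(fit_cohort.features[s], fit_cohort.labels[s])
                   for s in shardset.shards]
    return train_federated(shard_datas, validation, fed).best_params


def kfold_protocol(
    train_cohort: LabeledCohort,
    external_cohort: LabeledCohort,
    model_specs: list[ModelSpec],
    K: int = DEFAULT_K,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    on_fit=None,
) -> dict[str, CVSummary]:
    """Stratified K-fold benchmark of a model roster.

    ``on_fit``, if given, is called with the absolute row indices handed to
    every fitting routine; instrumented tests use it to confirm the holdout
    fold and the external cohort never leak into fitting.
    """
    if external_cohort.feature_names != train_cohort.feature_names:
        raise ValidationError("external cohort must share the training feature set")
    y = train_cohort.labels
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed % 2**32)
    summaries = {
        spec.name: CVSummary(spec.name, K, [], [], []) for spec in model_specs
    }
    for fold, (rest_idx, holdout_idx) in enumerate(
        skf.split(np.zeros(len(y)), y)
    ):
        fit_idx, val_idx = train_test_split(
            rest_idx, test_size=0.2, stratify=y[rest_idx],
            random_state=_derive(seed, fold) % 2**32,
        )
        if (np.intersect1d(fit_idx, holdout_idx).size
                or np.intersect1d(val_idx, holdout_idx).size):
            raise LeakageError(f"fold {fold}: holdout rows assigned to fitting")
        fit_cohort = train_cohort.subset(fit_idx, tag=f"fit_fold{fold}")
        standardizer = fit_standardizer(fit_cohort)
        fit_std = apply_standardizer(standardizer, fit_cohort)
        val_std = apply_standardizer(
            standardizer, train_cohort.subset(val_idx, tag="val"))
        holdout_std = apply_standardizer(
            standardizer, train_cohort.subset(holdout_idx, tag="holdout"))
        external_std = apply_standardizer(standardizer, external_cohort)
        validation = (val_std.features, val_std.labels)
        if on_fit is not None:
            on_fit(np.asarray(fit_idx))
        for mi, spec in enumerate(model_specs):
            t0 = time.perf_counter()
            params = _train_one(spec, fit_std, validation, _derive(seed, fold, mi))
            elapsed = time.perf_counter() - t0
            summary = summaries[spec.name]
            summary.runtime_seconds.append(elapsed)
            summary.internal.append(compute_metrics(
                holdout_std.labels, predict_scores(params, holdout_std.features),
                threshold))
            summary.external.append(compute_metrics(
                external_std.labels, predict_scores(params, external_std.features),
                threshold))
            logger.debug("fold %d model %s: internal AUC-PR %.4f (%.2fs)",
                         fold, spec.name, summary.internal[-1].auc_pr, elapsed)
        for s in summaries.values():
            s.fold_assignments.append({
                "holdout": np.asarray(holdout_idx), "fit": np.asarray(fit_idx),
                "val": np.asarray(val_idx),
            })
    return summaries


@dataclass
class RuntimeReport:
    seconds: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.seconds))

    @property
    def sd(self) -> float:
        return float(np.std(self.seconds, ddof=1)) if len(self.seconds) > 1 else 0.0

    @property
    def cv(self) -> float:
        return self.sd / self.mean if self.mean > 0 else 0.0


def measure_runtime(spec: ModelSpec, cohort: LabeledCohort, seed: int = 0,
                    reps: int = 1) -> RuntimeReport:
    """Wall-clock seconds from model initialization to trained model.

    Hardware-dependent by nature; reported for orientation only.
    """
    fit_idx, val_idx = train_test_split(
        np.arange(cohort.n_samples), test_size=0.2,
        stratify=cohort.labels, random_state=seed % 2**32)
    fit_cohort = cohort.subset(fit_idx)
    validation = (cohort.features[val_idx], cohort.labels[val_idx])
    times = []
    for rep in range(reps):
        t0 = time.perf_counter()
        _train_one(spec, fit_cohort, validation, _derive(seed, rep))
        times.append(time.perf_counter() - t0)
    return RuntimeReport(times)
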