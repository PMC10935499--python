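"""Training-set-fitted feature preparation.

Mirrors the usual multi-omics modeling pipeline after upstream calling and
normalisation: Z-scaling fitted on the training cohort only, linear
residualisation against caller-supplied covariates (the principal-component
adjustment analogue), and feature selection by extremely-randomised-trees
importance with correlation-based redundancy pruning.

Leakage guard: every fitting function in this module accepts only the
training cohort; fitted parameters are then applied verbatim to validation
and test cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from .cohort import LabeledCohort
from .config import DEFAULT_CORRELATION_CAP, DEFAULT_IMPORTANCE_QUANTILE, SD_FLOOR
from .exceptions import ValidationError


@dataclass
class StandardizerParams:
    """Per-feature location/scale fitted on a training cohort.

    The scale is the population standard deviation (divide by n); constant
    columns are floored at ``SD_FLOOR`` so they standardize to exactly zero.
    """

    mean: np.ndarray
    sd: np.ndarray
    feature_names: list[str]
    fitted_on: str = ""


def fit_standardizer(train: LabeledCohort) -> StandardizerParams:
    if train.n_samples == 0:
        raise ValidationError("cannot fit a standardizer on an empty cohort")
    mean = train.features.mean(axis=0)
    sd = train.features.std(axis=0, ddof=0)
    constant = sd < SD_FLOOR
    if constant.any():
        mean = mean.copy()
        sd = np.where(constant, SD_FLOOR, sd)
    return StandardizerParams(
        mean=mean, sd=sd, feature_names=train.feature_names, fitted_on=train.cohort_tag
    )


def apply_standardizer(params: StandardizerParams, cohort: LabeledCohort) -> LabeledCohort:
    """Apply fitted location/scale; never refits on the target cohort."""
    if params.feature_names != cohort.feature_names:
        missing = set(params.feature_names) ^ set(cohort.feature_names)
        raise ValidationError(f"feature-name mismatch; symmetric difference: {sorted(missing)}")
    z = (cohort.features - params.mean) / params.sd
    # constant columns: numerator is 0 up to float noise; pin to exactly 0
    z[:, params.sd <= SD_FLOOR] = 0.0
    out = cohort.subset(np.arange(cohort.n_samples))
    out.features = z
    return out


def residualize(cohort: LabeledCohort, covariates: np.ndarray) -> LabeledCohort:
    """Replace each feature by its OLS residual on covariates + intercept.

    Rank-deficient covariate matrices are rejected rather than silently
    pseudo-inverted.
    """
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != cohort.n_samples:
        raise ValidationError(
            f"covariate rows ({cov.shape[0]}) must align with cohort rows ({cohort.n_samples})"
        )
    if cov.shape[1] + 1 >= cohort.n_samples:
        raise ValidationError("covariate count must be < sample count")
    design = np.column_stack([np.ones(cov.shape[0]), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("covariate matrix (plus intercept) is rank-deficient")
    beta, *_ = np.linalg.lstsq(design, cohort.features, rcond=None)
    out = cohort.subset(np.arange(cohort.n_samples))
    out.features = cohort.features - design @ beta
    return out


@dataclass
class FeatureMask:
    """Outcome of importance-based selection with redundancy pruning."""

    kept: np.ndarray                      # sorted unique column indices
    importance: np.ndarray                # score per original feature
    pruning_log: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "kept": self.kept.tolist(),
            "importance": self.importance.tolist(),
            "pruning_log": self.pruning_log,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureMask":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["kept"], dtype=int),
                   np.asarray(d["importance"], dtype=float), d["pruning_log"])


def select_features(
    train: LabeledCohort,
    importance_quantile: float = DEFAULT_IMPORTANCE_QUANTILE,
    correlation_cap: float = DEFAULT_CORRELATION_CAP,
    seed: int = 0,
    n_estimators: int = 200,
) -> FeatureMask:
    """Rank features with an extra-trees classifier, drop the low-importance
    quantile, then greedily drop the lower-importance member of any pair
    whose squared correlation exceeds ``correlation_cap``.
    """
    if len(np.unique(train.labels)) < 2:
        raise ValidationError("feature selection needs both classes present")
    if not 0.0 < correlation_cap <= 1.0:
        raise ValidationError("correlation_cap must be in (0, 1]")
    forest = ExtraTreesClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    ).fit(train.features, train.labels)
    importance = forest.feature_importances_

    log: list[dict] = []
    threshold = float(np.quantile(importance, importance_quantile))
    keep = importance >= threshold if importance_quantile > 0 else np.ones_like(importance, bool)
    for j in np.flatnonzero(~keep):
        log.append({"feature": int(j), "reason": "low_importance", "partner": None})

    kept = np.flatnonzero(keep)
    if kept.size:
        sub = train.features[:, kept]
        sd = sub.std(axis=0, ddof=0)
        sd = np.where(sd < SD_FLOOR, SD_FLOOR, sd)
        corr = ((sub - sub.mean(0)) / sd).T @ ((sub - sub.mean(0)) / sd) / sub.shape[0]
        r2 = corr ** 2
        np.fill_diagonal(r2, 0.0)
        # visit pairs from the most correlated down; drop lower importance
        alive = np.ones(kept.size, dtype=bool)
        if correlation_cap < 1.0 or np.isclose(correlation_cap, 1.0):
            pairs = np.argwhere(np.triu(r2, k=1) > correlation_cap)
            order = np.argsort(-r2[pairs[:, 0], pairs[:, 1]], kind="stable")
            for a, b in pairs[order]:
                if alive[a] and alive[b]:
                    drop, partner = (a, b) if importance[kept[a]] <= importance[kept[b]] else (b, a)
                    alive[drop] = False
                    log.append({
                        "feature": int(kept[drop]),
                        "reason": "correlated",
                        "partner": int(kept[partner]),
                    })
        kept = kept[alive]

    if kept.size == 0:
        raise ValidationError(
            "feature mask is empty; relax importance_quantile or correlation_cap"
        )
    return FeatureMask(kept=np.sort(kept), importance=importance, pruning_log=log)


def apply_mask(mask: FeatureMask, cohort: LabeledCohort) -> LabeledCohort:
    out = LabeledCohort(
        features=cohort.features[:, mask.kept],
        labels=cohort.labels,
        feature_meta=cohort.feature_meta.iloc[mask.kept].reset_index(drop=True),
        cohort_tag=cohort.cohort_tag,
    )
    return out
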