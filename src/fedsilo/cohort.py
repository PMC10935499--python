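"""Synthetic labeled cohorts for multi-omics case/control benchmarking.

Real multi-omics Parkinson's cohorts of the kind this package benchmarks on
are access-controlled, so every experiment here runs on synthetic cohorts
that emulate the *post-preprocessing* state of such data: features already
covariate-adjusted and Z-scaled, split into a genetic-like block, a
transcriptomic-like block, and a small clinico-demographic block.

The generative family is class-conditional Gaussian with modular
equicorrelated sub-blocks inside each omics modality (co-expression-module
analogues of ~20 genes for the transcriptomic block, LD-block analogues of
~12 variants for the genetic block).  A sparse subset of the omics features
carries a
standardized mean difference between cases and controls; the clinical block
mirrors the fields commonly used in PD prediction (age, family history, an
ancestry flag, sex, and a smell-test score) with the smell-test analogue
carrying the largest single-feature effect, as it does in practice.

An "external" cohort can be drawn from the same feature space with
attenuated effects and a mean offset on the informative features, emulating
an out-of-distribution validation cohort collected after treatment onset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CohortParseError, ValidationError

MODALITIES = ("genetic", "transcriptomic", "clinical")

#: clinical-block effect template, in units of ``effect_scale``.
#: continuous effects are standardized mean differences (case - control);
#: binary effects are case-rate offsets added to the control rate.
_CLINICAL_TEMPLATE = (
    ("AGE", "continuous", 0.5),
    ("FAMILY_HISTORY", "binary", 0.15),
    ("AJ_STATUS", "binary", 0.03),
    ("SEX", "binary", 0.07),
    ("UPSIT", "continuous", -3.0),
)
_CLINICAL_BASE_RATES = {"FAMILY_HISTORY": 0.10, "AJ_STATUS": 0.02, "SEX": 0.63}

#: features per correlated sub-block: LD-block analogue for the genetic
#: modality, co-expression-module analogue for the transcriptomic one.
_BLOCK_WIDTHS = {"genetic": 12, "transcriptomic": 20}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``effect_scale`` is the mean absolute standardized effect of the
    informative omics features; ``block_correlation`` is the equicorrelation
    within each omics modality block.
    """

    n_cases: int
    n_controls: int
    n_genetic: int = 72
    n_transcriptomic: int = 596
    n_clinical: int = 5
    informative_fraction: float = 0.1
    effect_scale: float = 0.4
    block_correlation: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValidationError("n_cases must be >= 1")
        if self.n_controls < 1:
            raise ValidationError("n_controls must be >= 1")
        for name in ("n_genetic", "n_transcriptomic"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_clinical != len(_CLINICAL_TEMPLATE):
            raise ValidationError(
                f"n_clinical must be {len(_CLINICAL_TEMPLATE)} "
                "(age, family history, ancestry flag, sex, smell score)"
            )
        if not 0.0 < self.informative_fraction <= 1.0:
            raise ValidationError("informative_fraction must be in (0, 1]")
        if self.effect_scale < 0:
            raise ValidationError("effect_scale must be nonnegative")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValidationError("block_correlation must be in [0, 1)")

    @property
    def n_features(self) -> int:
        return self.n_genetic + self.n_transcriptomic + self.n_clinical


@dataclass(frozen=True)
class ShiftSpec:
    """Covariate shift applied when drawing an external cohort.

    ``effect_attenuation`` multiplies every class effect; ``mean_shift`` is
    added to the informative features of both classes.  The identity shift
    (attenuation 1, shift 0, no override) reproduces the source cohort
    exactly for the same seed.
    """

    mean_shift: float = 0.0
    effect_attenuation: float = 1.0
    label_ratio_override: tuple[int, int] | None = None

    def validate(self) -> None:
        if self.mean_shift < 0:
            raise ValidationError("mean_shift must be nonnegative")
        if not 0.0 <= self.effect_attenuation <= 1.0:
            raise ValidationError("effect_attenuation must be in [0, 1]")
        if self.label_ratio_override is not None:
            n_cases, n_controls = self.label_ratio_override
            if n_cases < 1 or n_controls < 1:
                raise ValidationError("label_ratio_override counts must be >= 1")


@dataclass
class LabeledCohort:
    """Samples x features with binary phenotype labels.

    ``feature_meta`` holds one row per feature column with its name and
    modality tag; ``labels`` uses 0 = control, 1 = case.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_meta: pd.DataFrame
    cohort_tag: str = ""
    #: truth from the generator (per-feature standardized effect); empty for
    #: cohorts read from disk.
    true_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-d matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ValidationError("labels length must equal feature-matrix row count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be binary 0/1")
        if np.isnan(self.features).any():
            raise ValidationError("features contain missing values")
        if len(self.feature_meta) != self.features.shape[1]:
            raise ValidationError("feature_meta length must equal feature count")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def feature_names(self) -> list[str]:
        return list(self.feature_meta["name"])

    def subset(self, indices: np.ndarray, tag: str | None = None) -> "LabeledCohort":
        """Row subset sharing feature metadata (used by splits and folds)."""
        idx = np.asarray(indices, dtype=np.intp)
        return LabeledCohort(
            features=self.features[idx],
            labels=self.labels[idx],
            feature_meta=self.feature_meta,
            cohort_tag=tag if tag is not None else self.cohort_tag,
            true_effects=self.true_effects,
        )


def _feature_meta(spec: CohortSpec) -> pd.DataFrame:
    names = (
        [f"GEN_{i:04d}" for i in range(spec.n_genetic)]
        + [f"TX_{i:04d}" for i in range(spec.n_transcriptomic)]
        + [name for name, _, _ in _CLINICAL_TEMPLATE]
    )
    modality = (
        ["genetic"] * spec.n_genetic
        + ["transcriptomic"] * spec.n_transcriptomic
        + ["clinical"] * spec.n_clinical
    )
    return pd.DataFrame({"name": names, "modality": modality})


def _omics_effects(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Sparse signed effect vector over the omics columns."""
    n_omics = spec.n_genetic + spec.n_transcriptomic
    m = max(1, round(spec.informative_fraction * n_omics))
    effects = np.zeros(n_omics)
    idx = rng.choice(n_omics, size=m, replace=False)
    signs = rng.choice((-1.0, 1.0), size=m)
    effects[idx] = signs * spec.effect_scale
    return effects


def _draw_class_block(
    n: int,
    effects: np.ndarray,
    sizes: tuple[int, int],
    rho: float,
    sign: float,
    mean_shift: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Omics features for one class: modular equicorrelated sub-blocks plus
    half the class effect."""
    cols = []
    for size, width in zip(sizes, (_BLOCK_WIDTHS["genetic"], _BLOCK_WIDTHS["transcriptomic"])):
        for start in range(0, size, width):
            w = min(width, size - start)
            factor = rng.standard_normal((n, 1))
            eps = rng.standard_normal((n, w))
            cols.append(math.sqrt(rho) * factor + math.sqrt(1.0 - rho) * eps)
    x = np.concatenate(cols, axis=1)
    # symmetric placement keeps the marginal mean near 0 regardless of the
    # case:control ratio, so an external cohort with a different ratio obeys
    # the same class-conditional law.
    return x + sign * effects / 2.0 + mean_shift


def _draw_clinical(
    n: int, is_case: bool, effect_scale: float, attenuation: float,
    mean_shift: float, rng: np.random.Generator,
) -> np.ndarray:
    cols = []
    sign = 1.0 if is_case else -1.0
    for name, kind, templ in _CLINICAL_TEMPLATE:
        if kind == "continuous":
            delta = templ * effect_scale * attenuation
            shift = mean_shift if effect_scale > 0 else 0.0
            cols.append(rng.standard_normal(n) + sign * delta / 2.0 + shift)
        else:
            base = _CLINICAL_BASE_RATES[name]
            rate = base + (templ * effect_scale * attenuation if is_case else 0.0)
            rate = float(np.clip(rate, 0.005, 0.995))
            cols.append(rng.binomial(1, rate, size=n).astype(float))
    return np.column_stack(cols)


def _generate(
    spec: CohortSpec, attenuation: float, mean_shift: float,
    n_cases: int, n_controls: int, tag: str,
) -> LabeledCohort:
    ss = np.random.SeedSequence(spec.seed)
    effect_rng, case_rng, control_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    omics_effects = _omics_effects(spec, effect_rng) * attenuation
    shift_vec = np.where(omics_effects != 0.0, mean_shift, 0.0)
    sizes = (spec.n_genetic, spec.n_transcriptomic)
    rho = spec.block_correlation

    blocks = []
    for n, is_case, rng in ((n_cases, True, case_rng), (n_controls, False, control_rng)):
        omics = _draw_class_block(
            n, omics_effects, sizes, rho, 1.0 if is_case else -1.0, shift_vec, rng
        )
        clinical = _draw_clinical(n, is_case, spec.effect_scale, attenuation, mean_shift, rng)
        blocks.append(np.hstack([omics, clinical]))

    features = np.vstack(blocks)
    labels = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    clinical_effects = np.array(
        [templ * spec.effect_scale if kind == "continuous" else templ * spec.effect_scale
         for _, kind, templ in _CLINICAL_TEMPLATE]
    )
    true_effects = np.concatenate([omics_effects, clinical_effects * attenuation])
    return LabeledCohort(
        features=features,
        labels=labels,
        feature_meta=_feature_meta(spec),
        cohort_tag=tag,
        true_effects=true_effects,
    )


def generate_cohort(spec: CohortSpec) -> LabeledCohort:
    """Draw a training-style cohort; deterministic for a fixed spec."""
    spec.validate()
    return _generate(spec, 1.0, 0.0, spec.n_cases, spec.n_controls, "internal")


def generate_external_cohort(spec: CohortSpec, shift: ShiftSpec) -> LabeledCohort:
    """Draw an external-validation cohort on the same feature space.

    Class separation is multiplied by ``shift.effect_attenuation`` and the
    informative features are offset by ``shift.mean_shift``; label counts may
    be overridden to emulate a differently balanced cohort.
    """
    spec.validate()
    shift.validate()
    if shift.label_ratio_override is not None:
        n_cases, n_controls = shift.label_ratio_override
    else:
        n_cases, n_controls = spec.n_cases, spec.n_controls
    return _generate(
        spec, shift.effect_attenuation, shift.mean_shift, n_cases, n_controls, "external"
    )


# --- on-disk dialect -----------------------------------------------------
# tab-separated, header row, first column sample ID, second column the 0/1
# label, remaining columns features; a JSON sidecar (<path>.meta.json)
# carries modality tags and generator provenance.  Floats are written with
# 17 significant digits so the round trip is exact for float64.


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_cohort(cohort: LabeledCohort, path: str | Path,
                 provenance: dict | None = None) -> None:
    path = Path(path)
    frame = pd.DataFrame(cohort.features, columns=cohort.feature_names)
    frame.insert(0, "label", cohort.labels)
    frame.insert(0, "sample_id", [f"S{i:06d}" for i in range(cohort.n_samples)])
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "cohort_tag": cohort.cohort_tag,
        "feature_meta": cohort.feature_meta.to_dict(orient="records"),
        "provenance": provenance or {},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_cohort(path: str | Path) -> LabeledCohort:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if frame.shape[1] < 3 or list(frame.columns[:2]) != ["sample_id", "label"]:
        raise CohortParseError(
            f"{path}: header must start with 'sample_id\\tlabel', got {list(frame.columns[:3])}"
        )
    labels = frame["label"]
    bad = labels[~labels.isin((0, 1))]
    if len(bad):
        row = int(bad.index[0])
        raise CohortParseError(
            f"{path}: non-binary label {bad.iloc[0]!r} at row {row + 2}, column 2"
        )
    values = frame.iloc[:, 2:]
    if values.isna().any().any() or not all(
        np.issubdtype(d, np.number) for d in values.dtypes
    ):
        col_mask = values.isna().any() | ~values.dtypes.map(lambda d: np.issubdtype(d, np.number))
        col = values.columns[col_mask][0]
        col_series = values[col]
        rows = col_series[col_series.isna()].index if col_series.isna().any() else col_series.index
        raise CohortParseError(
            f"{path}: missing or non-numeric value in column {col!r} at row {int(rows[0]) + 2}"
        )
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        feature_meta = pd.DataFrame(meta["feature_meta"])
        tag = meta.get("cohort_tag", "")
    else:
        feature_meta = pd.DataFrame(
            {"name": list(values.columns), "modality": "unknown"}
        )
        tag = path.stem
    if list(feature_meta["name"]) != list(values.columns):
        raise CohortParseError(f"{path}: sidecar feature names do not match header")
    return LabeledCohort(
        features=values.to_numpy(dtype=float),
        labels=labels.to_numpy(dtype=int),
        feature_meta=feature_meta,
        cohort_tag=tag,
    )


def spec_to_dict(spec: CohortSpec) -> dict:
    return asdict(spec)
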