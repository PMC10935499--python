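import numpy as np
import pandas as pd
import pytest

from fedsilo import CohortSpec, LabeledCohort, ShiftSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """A fast cohort spec: 80 samples, 40 features, clear signal."""
    return CohortSpec(
        n_cases=30, n_controls=50, n_genetic=10, n_transcriptomic=25,
        n_clinical=5, informative_fraction=0.2, effect_scale=1.0,
        block_correlation=0.2, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def study_cohort():
    """The default-size training cohort (598 x 673)."""
    return generate_cohort(CohortSpec(n_cases=171, n_controls=427, seed=7))


@pytest.fixture(scope="session")
def default_shift():
    return ShiftSpec(mean_shift=0.15, effect_attenuation=0.7,
                     label_ratio_override=(404, 712))


def labels_cohort(n_cases: int, n_controls: int, seed: int = 0) -> LabeledCohort:
    """Minimal one-feature cohort for splitter tests (rows shuffled)."""
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    rng.shuffle(labels)
    features = rng.standard_normal((n_cases + n_controls, 1))
    meta = pd.DataFrame({"name": ["F0"], "modality": ["clinical"]})
    return LabeledCohort(features=features, labels=labels, feature_meta=meta)
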