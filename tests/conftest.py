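import numpy as np
import pytest

import adwave as A


@pytest.fixture(scope="session")
def filters():
    return A.default_filter_set()


def _extract_cohort(effect_size: float, seed: int) -> A.FeatureMatrix:
    """Full-size study cohort (28 AD / 98 HC, 32 slices) -> feature matrix.

    Stacks are streamed through extraction one subject at a time to keep
    memory bounded.
    """
    spec = A.CohortSpec(effect_size=effect_size, seed=seed)
    labels = ["AD"] * spec.n_ad + ["HC"] * spec.n_hc
    stacks = (stack for _, _, stack, _ in A.cohort_arrays(spec))
    return A.build_feature_matrix_from_arrays(stacks, labels)


@pytest.fixture(scope="session")
def cohort_features():
    """Feature matrix of the separable cohort (effect size 2.0)."""
    return _extract_cohort(effect_size=2.0, seed=2026)


@pytest.fixture(scope="session")
def null_cohort_features():
    """Feature matrix of an exchangeable cohort (effect size 0)."""
    return _extract_cohort(effect_size=0.0, seed=2027)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
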