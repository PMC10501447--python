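import numpy as np
import pytest

from hyperfcn import HyperparameterGrid, RoiTimeSeries, SyntheticCohortSpec, generate_cohort
from hyperfcn.synthetic import cohort_feature_matrices


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_subject(rng):
    return RoiTimeSeries(
        rng.standard_normal((30, 8)), subject_id="subj", label=1
    )


@pytest.fixture(scope="session")
def reduced_grid():
    """Small hyperparameter grid keeping nested-CV tests fast."""
    return HyperparameterGrid(
        p_grid=np.array([0.01, 0.05]),
        lambda_grid=np.array([0.1, 0.5, 0.9]),
        gamma_grid=np.array([0.25, 1.0, 4.0]),
    )


def small_cohort_spec(effect_size: float, seed: int) -> SyntheticCohortSpec:
    """Scaled-down study conditions shared by the CV-level tests:
    40+40 subjects, 100 timepoints x 30 ROIs, 5 communities."""
    return SyntheticCohortSpec(
        n_per_group=(40, 40),
        n_timepoints=100,
        n_rois=30,
        n_blocks=5,
        effect_size=effect_size,
        seed=seed,
    )


@pytest.fixture(scope="session")
def signal_cohort_views():
    """One strongly separable cohort with its feature matrices at t = 0.7."""
    spec = small_cohort_spec(effect_size=0.5, seed=7)
    cohort, truth = generate_cohort(spec)
    views, labels, ids = cohort_feature_matrices(cohort, 0.7)
    return cohort, truth, views, labels, ids
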