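import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adductrisk as ar

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Cohort seed used by the shared study-scale fixtures.
COHORT_SEED = 7
#: Training seed used by the shared full fit.
TRAIN_SEED = 0


@pytest.fixture(scope="session")
def default_cohort():
    """A study-sized synthetic cohort: 152 cases, 71 controls."""
    return ar.generate_cohort(ar.default_config(152, 71, seed=COHORT_SEED))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort (30 cases / 15 controls) for I/O and plumbing tests."""
    return ar.generate_cohort(ar.default_config(30, 15, seed=3))


@pytest.fixture(scope="session")
def fast_tconfig():
    """Abbreviated training schedule for structural (non-convergence) checks."""
    return ar.TrainingConfig(n_updates=2000, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def full_fit(default_cohort):
    """Full-panel fit of the study-sized cohort at the study hyperparameters.

    Session-scoped: the 50 000-update training runs once and is shared by
    the separability and operating-point tests.
    """
    return ar.run_case_full(
        default_cohort, ar.FULL_SUBSET, ar.TrainingConfig(seed=TRAIN_SEED)
    )


@pytest.fixture(scope="session")
def full_cv(default_cohort):
    """20-repeat stratified 80/20 holdout of the full panel (study settings)."""
    return ar.cross_validate(
        default_cohort,
        ar.FULL_SUBSET,
        ar.TrainingConfig(seed=TRAIN_SEED),
        ar.CVConfig(train_fraction=0.8, n_repeats=20, seed=11),
    )


def shuffle_labels(records, seed):
    """Reassign the group labels at random, preserving the class counts."""
    rng = np.random.default_rng(seed)
    labels = np.array([r.group for r in records])
    rng.shuffle(labels)
    return [
        ar.SubjectRecord(
            subject_id=r.subject_id,
            group=str(label),
            conc_hb_34q=r.conc_hb_34q,
            conc_hb_23q=r.conc_hb_23q,
            conc_alb_34q=r.conc_alb_34q,
            conc_alb_23q=r.conc_alb_23q,
        )
        for r, label in zip(records, labels)
    ]
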