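import numpy as np
import pytest

from cofluct import SyntheticCohortSpec, generate_cohort, score_scan


def make_random_scan(rng, n_frames=200, n_regions=12):
    """Unstructured random scan for oracle tests."""
    from cofluct import standardize_scan

    return standardize_scan(rng.standard_normal((n_frames, n_regions)))


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 6-subject cohort shared across module tests."""
    spec = SyntheticCohortSpec(
        n_subjects=6, n_regions_per_class=(6, 6, 6), n_frames=600, seed=11
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_scores(small_cohort):
    return [score_scan(s) for s in small_cohort.scans]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
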