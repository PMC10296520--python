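import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dcefoci.cohort import CohortParams, generate_cohort  # noqa: E402

#: Reduced-resolution grid used throughout the suite to keep desk runtimes.
TEST_SHAPE = (12, 64, 64)


def tiny_params(**overrides) -> CohortParams:
    defaults = dict(
        n_cancer_with_abnormality=4,
        n_cancer_without=2,
        n_cancer_free=5,
        volume_shape=TEST_SHAPE,
        seed=3,
    )
    defaults.update(overrides)
    return CohortParams(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """A small on-disk cohort shared by I/O-heavy tests."""
    root = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(tiny_params(), root)
    return manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
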