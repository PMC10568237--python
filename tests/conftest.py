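import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def nsr_recording():
    """One noiseless 60 s synthetic NSR ECG with its planted beat positions."""
    from afibkit.synthetic import SyntheticSpec, synthesize_recording

    spec = SyntheticSpec(rhythm="NSR", seed=11)
    return synthesize_recording(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject synthetic cohort shared by the slower integration tests."""
    from afibkit.synthetic import make_cohort

    return make_cohort(12, 0.5, seed=7)
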