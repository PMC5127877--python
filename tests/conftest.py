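import numpy as np
import pytest

from dwirep import AcquisitionProtocol, PhantomSpec


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    """The six-b clinical scheme used throughout."""
    return AcquisitionProtocol((0, 50, 100, 300, 600, 1000))


@pytest.fixture
def tiny_spec() -> PhantomSpec:
    """Small noise-free mono phantom for fast exact checks."""
    return PhantomSpec(
        grid_shape=(10, 10, 5),
        roi_radius_frac=0.3,
        n_subjects=3,
        snr=None,
        retest_log_sd=0.0,
        subject_log_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
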