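"""Shared fixtures: synthetic femora, phantom, and calibration models.

Expensive volume renders are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from hipbmd import (
    AcquisitionSpec,
    FemurSpec,
    build_femur,
    build_phantom,
    make_fixed_calibration,
    reference_abmd,
)

#: Coarse acquisition for tests where sub-millimetre accuracy is irrelevant.
COARSE = AcquisitionSpec(noise_sd=0.0, seed=7, voxel_size=(1.5, 1.5, 1.5))


@pytest.fixture(scope="session")
def default_spec():
    return FemurSpec()


@pytest.fixture(scope="session")
def neutral_bundle(default_spec):
    """Noiseless femur at neutral pose, default acquisition resolution."""
    return build_femur(default_spec, AcquisitionSpec(noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def coarse_bundle(default_spec):
    return build_femur(default_spec, COARSE)


@pytest.fixture(scope="session")
def phantom_bundle():
    """Noiseless B-MAS200-style phantom; HU = 0.8 * density - 10."""
    return build_phantom(acq=AcquisitionSpec(noise_sd=0.0, seed=1))


@pytest.fixture(scope="session")
def exact_model():
    """Exact inverse of the default synthetic HU map (0.8, -10)."""
    return make_fixed_calibration(1.25, 12.5)


@pytest.fixture(scope="session")
def oracle_abmd(default_spec):
    return reference_abmd(default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
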