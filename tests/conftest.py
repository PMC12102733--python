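import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from inhibkin import AssayDesign, KineticParameters, build_rate_table, simulate_plate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# uninhibited constants of the worked example
KM0, VMAX0 = 93.9, 33.02


@pytest.fixture(scope="session")
def uncompetitive_truth() -> KineticParameters:
    return KineticParameters(km=KM0, vmax=VMAX0, ki_prime=44.3)


@pytest.fixture(scope="session")
def competitive_truth() -> KineticParameters:
    return KineticParameters(km=KM0, vmax=VMAX0, ki=30.0)


@pytest.fixture(scope="session")
def noncompetitive_truth() -> KineticParameters:
    return KineticParameters(km=KM0, vmax=VMAX0, ki=50.0, ki_prime=50.0)


def noiseless_design(**overrides) -> AssayDesign:
    """Constant-rate, noise-free design used for exactness checks."""
    base = dict(noise_sd=0.0, depletion=False, seed=0)
    base.update(overrides)
    return AssayDesign(**base)


def noiseless_table(truth: KineticParameters, **overrides):
    design = noiseless_design(**overrides)
    plate = simulate_plate(design, truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_rate_table(plate, design.gain, design.enzyme_mass)


@pytest.fixture(scope="session")
def uncompetitive_table(uncompetitive_truth):
    return noiseless_table(uncompetitive_truth)


@pytest.fixture(scope="session")
def competitive_table(competitive_truth):
    return noiseless_table(competitive_truth)


@pytest.fixture(scope="session")
def noncompetitive_table(noncompetitive_truth):
    return noiseless_table(noncompetitive_truth)
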