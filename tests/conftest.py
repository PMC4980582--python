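"""Shared fixtures: calibrated profile and common-random-number runs.

The expensive artifacts (calibration, the 13-policy sweep at 100
replications) are computed once per session and shared by the metric,
policy-comparison, and acceptance tests.
"""

import pytest
from hypothesis import settings as hyp_settings

from ctqsim import (
    PolicyConfig,
    SimConfig,
    calibrate,
    compare_policies,
    default_profile,
)

hyp_settings.register_profile("repro", derandomize=True)
hyp_settings.load_profile("repro")

CALIBRATION_SEED = 1
RUN_SEED = 424242  # distinct from the pilot seed: held-out replications


@pytest.fixture(scope="session")
def calibration():
    return calibrate(default_profile(), seed=CALIBRATION_SEED)


@pytest.fixture(scope="session")
def calibrated_profile(calibration):
    return calibration.profile


@pytest.fixture(scope="session")
def sweep_comparison(calibrated_profile):
    """base + fixed P=0..10 + dynamic, 100 CRN days on the calibrated profile."""
    sim = SimConfig(
        policy=PolicyConfig(kind="base"),
        profile=calibrated_profile,
        n_reps=100,
        master_seed=RUN_SEED,
    )
    policies = (
        [PolicyConfig(kind="base")]
        + [PolicyConfig(kind="fixed", P=p) for p in range(11)]
        + [PolicyConfig(kind="dynamic")]
    )
    return compare_policies(sim, policies)
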