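"""Shared fixtures: one noise-free random-mount rig, its alignment, and
cached zero-noise simulations of every test (expensive pieces are
session-scoped so the suite stays fast)."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lumbokin as lk
from lumbokin import simulate as sim
from lumbokin.types import TestId

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

MOVEMENT_TESTS = [t for t in TestId if t is not TestId.SYNC]


def noisefree_rig(seed: int) -> sim.RigConfig:
    """Random mounts (<= 15 deg) but zero sensor noise."""
    return sim.RigConfig(seed=seed, gyro_noise_sd=0.0, orient_noise_sd=0.0,
                         accel_noise_sd=0.0)


@pytest.fixture(scope="session")
def rig0() -> sim.RigConfig:
    return noisefree_rig(5)


@pytest.fixture(scope="session")
def sync_sim(rig0):
    return sim.simulate_trial(sim.make_motion_script(TestId.SYNC), rig0)


@pytest.fixture(scope="session")
def align0(sync_sim):
    rec, _ = sync_sim
    result = lk.align_trial(rec)
    assert not result.errors
    return result


@pytest.fixture(scope="session")
def sims(rig0):
    """Zero-noise recording + ground truth for each of the nine tests."""
    return {t: sim.simulate_trial(sim.make_motion_script(t), rig0)
            for t in MOVEMENT_TESTS}


@pytest.fixture(scope="session")
def angles_of(sims, align0):
    """Pair -> EulerSeries maps for each test, computed once."""
    cache = {}

    def get(test_id: TestId):
        if test_id not in cache:
            rec, _ = sims[test_id]
            angles, omitted = lk.compute_segment_angles(rec, align0)
            assert not omitted
            cache[test_id] = angles
        return cache[test_id]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
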