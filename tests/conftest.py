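"""Shared fixtures: small synthetic sessions and brute-force oracles."""

import numpy as np
import pytest

from licklock.core_io import LickTrain
from licklock.synth import BehaviourSpec, CellSpec, generate_licks, generate_session


@pytest.fixture(scope="session")
def behaviour():
    return BehaviourSpec()


@pytest.fixture(scope="session")
def licks_600(behaviour):
    """One 600 s behavioural realisation reused by read-only analyses."""
    return generate_licks(behaviour, 600.0, 12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(987)


def random_lick_train(rng, n=40, duration=60.0):
    t = np.sort(rng.uniform(0, duration, size=n))
    t = t[np.concatenate(([True], np.diff(t) > 1e-6))]
    return LickTrain(detect_times=t, session_duration=duration)


def brute_force_bouts(times, max_gap):
    """Independent gap-scan oracle for bout partitioning."""
    if len(times) == 0:
        return []
    groups = [[0]]
    for i in range(1, len(times)):
        if times[i] - times[i - 1] < max_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [(g[0], g[-1]) for g in groups]
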