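"""Shared fixtures: channel tables, the default path, and a simulated adult
reference cohort (session-scoped — fitting it once keeps the suite fast)."""
from __future__ import annotations

import numpy as np
import pytest

import svmckit as sk


@pytest.fixture(scope="session")
def le_table():
    return sk.load_channel_table("LE")


@pytest.fixture(scope="session")
def ue_table():
    return sk.load_channel_table("UE")


@pytest.fixture(scope="session")
def default_path():
    return sk.generate_target_path()


@pytest.fixture(scope="session")
def nia_sessions(default_path):
    """30 simulated neurologically intact adults, ankle_L target (the
    recruitment target of the reference cohort)."""
    return sk.simulate_cohort(30, "NIA", seed=20_001, path=default_path)


@pytest.fixture(scope="session")
def nia_reference(nia_sessions):
    processed = [sk.process_sim_session(s) for s in nia_sessions]
    return sk.NormativeReference.fit(processed)


def make_channel(angle, rate_hz=29.0, name="ankle_L", t0=0.0):
    angle = np.asarray(angle, dtype=float)
    t = t0 + np.arange(angle.size) / rate_hz
    return sk.JointChannel(name=name, t=t, angle=angle, rate_hz=rate_hz)


@pytest.fixture
def channel_factory():
    return make_channel
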