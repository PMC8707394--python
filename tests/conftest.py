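from datetime import datetime

import numpy as np
import pytest

from actibed.signal_features import TriaxialRecording, build_features


START = datetime(2018, 10, 1, 20, 0, 0)


def constant_recording(site, vector, seconds=60.0, hz=50.0, start=START):
    n = int(round(seconds * hz))
    samples = np.tile(np.asarray(vector, dtype=float), (n, 1))
    return TriaxialRecording(site=site, start_time=start, sample_rate=hz, samples=samples)


@pytest.fixture
def lying_pair():
    """Hip flat on its side (90 deg), thigh horizontal and still: lying."""
    hip = constant_recording("hip", (0.0, 1.0, 0.0))
    thigh = constant_recording("thigh", (0.01, 1.0, 0.0))
    return hip, thigh


@pytest.fixture
def upright_pair():
    """Both devices aligned with gravity: standing upright."""
    hip = constant_recording("hip", (1.0, 0.0, 0.0))
    thigh = constant_recording("thigh", (1.0, 0.01, 0.0))
    return hip, thigh


@pytest.fixture
def lying_features(lying_pair):
    return build_features(*lying_pair)
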