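import numpy as np
import pytest

from pupiltag import SimulationParams, StimulusSchedule


@pytest.fixture
def schedule():
    """Short 60 s block at the design parameters (1.7 Hz, 180 deg)."""
    return StimulusSchedule(block_duration_s=60.0)


@pytest.fixture
def sim_params():
    return SimulationParams(seed=12345)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


def make_trace(pupil, sample_rate=1000.0, valid=None, blink=None, **kw):
    """Helper: build a PupilTrace from a pupil vector."""
    from pupiltag import PupilTrace

    pupil = np.asarray(pupil, dtype=float)
    n = len(pupil)
    return PupilTrace(
        times=np.arange(n) * 1000.0 / sample_rate,
        pupil=pupil,
        valid=np.ones(n, bool) if valid is None else np.asarray(valid, bool),
        sample_rate=sample_rate,
        blink=blink,
        **kw,
    )
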