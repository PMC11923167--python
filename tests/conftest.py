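import numpy as np
import pytest

from stridefiber import AnalysisParams, BehaviorTrack, SynthConfig


@pytest.fixture(scope="session")
def params() -> AnalysisParams:
    return AnalysisParams()


@pytest.fixture
def small_config() -> SynthConfig:
    """Short low-rate session, quick enough for per-test simulation."""
    return SynthConfig(duration=120.0, rate=200.0, seed=7)


def make_track(v: np.ndarray, rate: float = 100.0, motion_index=None) -> BehaviorTrack:
    t = np.arange(len(v)) / rate
    return BehaviorTrack(t=t, velocity=np.asarray(v, float), motion_index=motion_index)


@pytest.fixture
def track_factory():
    return make_track
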