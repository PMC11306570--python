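import numpy as np
import pytest

from contagionkit import Landmarks, SimConfig
from contagionkit.core import SampledStream


@pytest.fixture
def symmetric_landmarks() -> Landmarks:
    """Hand-placed symmetric face landmarks on a 200x240 frame."""
    return Landmarks(
        image_id="fixture",
        width=200,
        height=240,
        eyebrow_left=np.array([[50, 80], [60, 76], [70, 74], [80, 76], [90, 80]]),
        eyebrow_right=np.array([[110, 80], [120, 76], [130, 74], [140, 76], [150, 80]]),
        cheek_left=np.array([40, 130]),
        cheek_right=np.array([160, 130]),
        eye_left=np.array([70, 100]),
        eye_right=np.array([130, 100]),
    )


@pytest.fixture
def small_config() -> SimConfig:
    """A small but structurally complete cohort configuration."""
    return SimConfig(n_participants=3, seed=11)


def make_trace(values, rate=120.0, mask=None) -> SampledStream:
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) / rate
    return SampledStream(t, values, mask)


@pytest.fixture
def trace_factory():
    return make_trace
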