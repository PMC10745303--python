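import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from tremorvideo import AnalysisConfig, TrajectorySeries


@pytest.fixture
def config():
    return AnalysisConfig()


def make_sinusoid_traj(
    frequency=4.0,
    half_amplitude=10.0,
    fps=25.0,
    duration=60.0,
    axis_deg=0.0,
    envelope=None,
    phase=0.0,
    drift=0.0,
):
    """A clean planar sinusoidal trajectory for oracle-style tests."""
    n = int(round(duration * fps)) + 1
    t = np.arange(n) / fps
    s = half_amplitude * np.sin(2 * np.pi * frequency * t + phase)
    if envelope is not None:
        s = s * envelope(t)
    th = np.deg2rad(axis_deg)
    return TrajectorySeries(
        x=s * np.cos(th) + drift * t, y=s * np.sin(th), fps=fps, units="mm"
    )


@pytest.fixture
def sinusoid_factory():
    return make_sinusoid_traj
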