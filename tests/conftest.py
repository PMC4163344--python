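import numpy as np
import pytest

from cprspec.signal_io import AccelerationRecord, DisplacementRecord
from cprspec.spectral import AnalysisWindow

FS = 100.0


def tone_window(freq: float, amp: float = 1.0, tw: float = 3.0, fs: float = FS,
                phase: float = 0.0) -> AnalysisWindow:
    """Pure-cosine analysis window, the basic spectral test input."""
    t = np.arange(int(round(tw * fs))) / fs
    return AnalysisWindow(start=0.0, duration=tw, samples=amp * np.cos(2 * np.pi * freq * t + phase), fs=fs)


def sinusoidal_compression_accel(rate_min: float, depth_mm: float, tw: float = 3.0,
                                 fs: float = FS) -> AnalysisWindow:
    """Acceleration of a sinusoidal compression: depth_mm peak-to-peak at rate_min.

    Closed form: s(t) = (depth/2) cos(2 pi f t) mm -> a(t) = -(2 pi f)^2 (depth/2000) cos(...) m/s^2.
    """
    f = rate_min / 60.0
    amp = (2 * np.pi * f) ** 2 * (depth_mm / 2000.0)
    t = np.arange(int(round(tw * fs))) / fs
    return AnalysisWindow(0.0, tw, -amp * np.cos(2 * np.pi * f * t), fs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def accel_record(rng):
    """60 s triaxial record: 2 Hz compression on z plus noise."""
    t = np.arange(int(60 * FS)) / FS
    z = 2.5 * np.cos(2 * np.pi * 2.0 * t) + 9.81
    xy = rng.normal(0, 0.05, size=(len(t), 2))
    return AccelerationRecord(np.column_stack([xy, z]), fs=FS)


@pytest.fixture
def displacement_record():
    """60 s displacement: 50 mm peak-to-peak at 100 min^-1."""
    t = np.arange(int(60 * FS)) / FS
    return DisplacementRecord(25.0 * (1 - np.cos(2 * np.pi * (100 / 60) * t)), fs=FS)
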