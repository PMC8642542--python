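import numpy as np
import pandas as pd
import pytest

from hydroscape.calibration import CalibratedSegment, DeploymentMetadata

T0 = pd.Timestamp("2019-06-01T00:00:00")


@pytest.fixture
def meta_8k() -> DeploymentMetadata:
    return DeploymentMetadata(
        station_id="TST",
        sample_rate=8192,
        deployment_start=T0,
        deployment_end=T0 + pd.Timedelta(days=10),
    )


def make_segment(x: np.ndarray, fs: int = 8192,
                 start: pd.Timestamp = T0) -> CalibratedSegment:
    return CalibratedSegment(np.asarray(x, dtype=float), start, fs)


@pytest.fixture
def tone_segment() -> CalibratedSegment:
    """10 s of a 250 Hz tone with RMS 1 Pa (10^6 µPa) → 120 dB re 1 µPa."""
    fs = 8192
    t = np.arange(10 * fs) / fs
    return make_segment(1e6 * np.sqrt(2.0) * np.sin(2 * np.pi * 250.0 * t), fs)
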