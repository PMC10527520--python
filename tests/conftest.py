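import numpy as np
import pandas as pd
import pytest

from smlmpatterns import ROI, LocalizationTable


@pytest.fixture
def roi4um() -> ROI:
    """4 um x 4 um analysis window in nm."""
    return ROI(0.0, 4000.0, 0.0, 4000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230822)


def make_table(
    x, y, frame=None, z=None, channel=None, intensity=None, frame_rate=13.4
) -> LocalizationTable:
    n = len(x)
    data = {
        "frame": np.zeros(n, dtype=np.int64) if frame is None else np.asarray(frame, dtype=np.int64),
        "x": np.asarray(x, dtype=float),
        "y": np.asarray(y, dtype=float),
    }
    if z is not None:
        data["z"] = np.asarray(z, dtype=float)
    if channel is not None:
        data["channel"] = np.asarray(channel, dtype=np.int64)
    if intensity is not None:
        data["intensity"] = np.asarray(intensity, dtype=float)
    return LocalizationTable(pd.DataFrame(data), frame_rate=frame_rate)
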