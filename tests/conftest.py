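import numpy as np
import pandas as pd
import pytest

from vectionerp import standard_layout
from vectionerp.preprocessing import EpochSet


@pytest.fixture(scope="session")
def layout():
    return standard_layout()


@pytest.fixture(scope="session")
def layout64(layout):
    return layout


def make_epochs(
    data: np.ndarray,
    channels: list[str],
    conditions: list[str] | None = None,
    srate: float = 1000.0,
    tmin_ms: float = -200.0,
) -> EpochSet:
    """Build an EpochSet around a raw (epochs, channels, time) array."""
    n_ep, n_ch, n_t = data.shape
    conditions = conditions or ["coherent"] * n_ep
    labels = pd.DataFrame(
        {
            "condition": conditions,
            "direction": ["cw"] * n_ep,
            "subject": ["s01"] * n_ep,
            "group": ["left"] * n_ep,
        }
    )
    times = tmin_ms + np.arange(n_t) / srate * 1000.0
    return EpochSet(data=data, times=times, channel_labels=channels, labels=labels, srate=srate)
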