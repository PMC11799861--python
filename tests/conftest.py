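import numpy as np
import pandas as pd
import pytest

from cfserp.synth import EpochSet, TrialSchedule, default_times, make_layout


@pytest.fixture(scope="session")
def layout16():
    return make_layout(16)


@pytest.fixture(scope="session")
def layout64():
    return make_layout(64)


def make_epochs(data, sampling_rate=500.0, labels=None, channel_names=None):
    """EpochSet from a raw (S, T, C, time) array with default metadata."""
    data = np.asarray(data, dtype=np.float64)
    n_times = data.shape[3]
    times = default_times(sampling_rate)[:n_times]
    if labels is None:
        labels = pd.DataFrame(
            {
                "trial": np.arange(data.shape[1]),
                "block": 1,
                "expression": "neutral",
                "contrast_level": "high",
                "contrast_value": 0.3,
                "cfs": True,
                "prompt": False,
            }
        )
    return EpochSet(
        data=data,
        times=times,
        labels=labels,
        sampling_rate=sampling_rate,
        channel_names=channel_names
        or [f"E{i:03d}" for i in range(data.shape[2])],
    )


def two_condition_schedule(n_per_condition, level="high", cfs=True, contrast=0.3):
    """Fearful + neutral trials of a single cell, for targeted ERP checks."""
    n = 2 * n_per_condition
    table = pd.DataFrame(
        {
            "trial": np.arange(n),
            "block": 1,
            "expression": ["fearful"] * n_per_condition
            + ["neutral"] * n_per_condition,
            "contrast_level": level,
            "contrast_value": contrast,
            "cfs": cfs,
            "prompt": False,
        }
    )
    return TrialSchedule(table=table, contrasts={level: contrast})
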