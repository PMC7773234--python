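import numpy as np
import pandas as pd
import pytest

import brushtrack as bt


@pytest.fixture(scope="session")
def zero_noise_session():
    """One deterministic session with all noise off: VO == MT after binning."""
    profile = bt.make_profile("habitual", total_duration_s=60.0)
    return bt.simulate_session(profile, bt.NoiseModel.zero(), seed=12345)


@pytest.fixture(scope="session")
def noisy_session():
    profile = bt.make_profile("habitual", total_duration_s=60.0)
    return bt.simulate_session(profile, bt.NoiseModel(), seed=777)


def intervals_from_labels(labels, bin_s=0.5):
    """Build an aggregated interval table directly from a label sequence
    (one interval per label), for metric tests that bypass binning."""
    n = len(labels)
    return pd.DataFrame(
        {
            "index": np.arange(n),
            "start_s": np.arange(n) * bin_s,
            "end_s": (np.arange(n) + 1) * bin_s,
            "label": list(labels),
            "support": 1,
        }
    )


@pytest.fixture
def make_intervals():
    return intervals_from_labels


def make_paired(vo_labels, mt_labels, **meta):
    n = len(vo_labels)
    table = pd.DataFrame(
        {
            "index": np.arange(n),
            "vo_label": list(vo_labels),
            "mt_label": list(mt_labels),
        }
    )
    kwargs = dict(subject_id="S001", session="baseline", brush="manual")
    kwargs.update(meta)
    return bt.PairedIntervalTable(table=table, **kwargs)


@pytest.fixture
def paired_factory():
    return make_paired
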