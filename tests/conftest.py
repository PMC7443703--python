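import warnings

import numpy as np
import pytest

from megdbs.phantom import SimConfig, make_condition_set, make_sensor_array
from megdbs.evaluation import preprocess_conditions

# mne emits deprecation chatter about random_state; irrelevant here
warnings.filterwarnings("ignore", message="Use rng=")


@pytest.fixture(scope="session")
def sensors128():
    return make_sensor_array(128, 0.12, seed=1)


@pytest.fixture(scope="session")
def sensors64():
    return make_sensor_array(64, 0.12, seed=2)


@pytest.fixture(scope="session")
def tiny_config():
    # small, fast session: fixed stimulation gain skips the calibration search
    return SimConfig(duration=10.0, n_channels=32, seed=11, stim_gain=4e-13)


@pytest.fixture(scope="session")
def tiny_set(tiny_config):
    return make_condition_set(tiny_config)


@pytest.fixture(scope="session")
def eval_config():
    """Full-size evaluation session (128 channels), scaled to 60 s for throughput."""
    return SimConfig(duration=60.0, n_channels=128, seed=5)


@pytest.fixture(scope="session")
def eval_set(eval_config):
    return preprocess_conditions(make_condition_set(eval_config))


@pytest.fixture(scope="session")
def eval_sweeps(eval_set):
    """All four method sweeps on the evaluation session (shared: expensive)."""
    from megdbs.spectral import welch_psd
    from megdbs.evaluation import (BandSet, DEFAULT_SWEEPS, detect_dbs_peak,
                                   sweep)

    f_peak = detect_dbs_peak(welch_psd(eval_set.dsmw))
    bands = BandSet(f_peak=f_peak)
    sweeps = {m: sweep(m, DEFAULT_SWEEPS[m], eval_set, bands, seed=7)
              for m in ("hampel", "s3p", "icami", "tsss")}
    return bands, sweeps
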