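import numpy as np
import pandas as pd
import pytest

from thermofeed import SimConfig, TemperatureTrace, simulate_herd, write_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_cows=40, trial_days=14, seed=42)


@pytest.fixture(scope="session")
def small_herd(small_config):
    """One shared small synthetic herd; tests must not mutate it."""
    return simulate_herd(small_config)


@pytest.fixture(scope="session")
def herd_dir(small_herd, tmp_path_factory):
    """The small herd written out in the pipeline's input schema."""
    d = tmp_path_factory.mktemp("herd")
    write_dataset(small_herd, d)
    return d


def make_trace(values, cow_id="cow", start="2022-06-01", step_min=5):
    values = np.asarray(values, dtype=float)
    times = pd.date_range(start, periods=len(values), freq=f"{step_min}min")
    return TemperatureTrace(cow_id=cow_id, times=times, values=values)


@pytest.fixture
def trace_factory():
    return make_trace
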