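import numpy as np
import pandas as pd
import pytest

from flucdyn import GeneratorConfig, TraceSet


@pytest.fixture
def config():
    return GeneratorConfig(seed=1234)


@pytest.fixture
def noise_free_config(config):
    return config.replace(obs_cv=0.0, log_sd=0.0)


def build_trace_frame(records, units=None):
    """Build a TraceSet from (cell, frame, t, channel, intensity, bg, cycle, div) tuples."""
    df = pd.DataFrame(
        records,
        columns=[
            "cell_id",
            "frame",
            "time_h",
            "channel",
            "intensity",
            "background",
            "cycle_id",
            "division_flag",
        ],
    )
    return TraceSet(df, units=units or {})


@pytest.fixture
def simple_cycle_traces():
    """One cell, one complete 4-h cycle sampled hourly, linear ramp a -> 2a."""
    a = 10.0
    records = [
        ("c0", k, float(k), "SOX2", a * (1 + k / 4.0), 0.0, 0, 1 if k == 4 else 0)
        for k in range(5)
    ]
    return build_trace_frame(records)


def rng_for(seed):
    return np.random.default_rng(seed)
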