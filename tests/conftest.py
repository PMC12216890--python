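import numpy as np
import pandas as pd
import pytest

import gaitspace as g


@pytest.fixture(scope="session")
def small_config():
    return g.SynthConfig(n_tasks=3, cycles_per_task=15, n_channels=16,
                         n_ti_latents=3, n_td_latents=3, harmonic_order=5,
                         noise_sd=1.0, seed=11)


@pytest.fixture(scope="session")
def small_session(small_config):
    session, truth = g.generate_session(small_config)
    return session, truth


@pytest.fixture(scope="session")
def small_tensor(small_session):
    session, _ = small_session
    _, tensor, _ = g.cli_io.prepare_region(session, "source")
    return tensor


@pytest.fixture(scope="session")
def noiseless_session():
    cfg = g.SynthConfig(n_tasks=3, cycles_per_task=12, n_channels=16,
                        n_ti_latents=3, n_td_latents=3, harmonic_order=5,
                        noise_sd=0.0, seed=5)
    session, truth = g.generate_session(cfg)
    _, tensor, _ = g.cli_io.prepare_region(session, "source")
    return session, truth, tensor


def make_events(rows):
    return g.GaitEventTable(pd.DataFrame(
        rows, columns=["task_id", "cycle_index", "t_strike_start",
                       "t_foot_off", "t_strike_end"]))


@pytest.fixture
def simple_events():
    """12 clean 1 s cycles (0.6 s stance) in one task, starting at t=1."""
    rows = [("walk", i, 1.0 + i, 1.6 + i, 2.0 + i) for i in range(12)]
    return make_events(rows)
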