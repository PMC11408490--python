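"""Shared fixtures: small synthetic sessions and neuron populations."""

import numpy as np
import pandas as pd
import pytest

from dopabid import neural, synth


@pytest.fixture(scope="session")
def small_trials() -> pd.DataFrame:
    """Four 300-trial sessions of the larger-reward-set subject."""
    cfg = synth.SubjectConfig(name="V", n_sessions=4, trials_per_session=300)
    trials, _ = synth.simulate_behavior(cfg, seed=101)
    return trials


@pytest.fixture(scope="session")
def bid_population(small_trials):
    """Twelve bid-coding neurons simulated over the full trial set."""
    return synth.simulate_population(small_trials, 12, coding_target="bid", seed=102)


@pytest.fixture(scope="session")
def bid_responses(small_trials, bid_population) -> pd.DataFrame:
    window = neural.AnalysisWindow(180, 340)
    return neural.build_response_table(bid_population, small_trials, window)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
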