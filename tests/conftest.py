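"""Shared fixtures: small seeded synthetic sessions, preprocessed once."""

from __future__ import annotations

import numpy as np
import pytest

from navcode import behavior_analysis as ba
from navcode import trace_processing as tp
from navcode.synthetic_session import (
    SimConfig,
    high_snr_config,
    simulate_behavior,
    simulate_place_cells,
)


class Session:
    """Bundle of one simulated + preprocessed treadmill session."""

    def __init__(self, config: SimConfig, centers=None):
        self.config = config
        self.behavior = simulate_behavior(config)
        self.traces, self.truth = simulate_place_cells(self.behavior, config, centers)
        self.dff, self.events = tp.preprocess(self.traces)
        self.epochs = ba.detect_running_epochs(self.behavior)


@pytest.fixture(scope="session")
def small_tuned_session() -> Session:
    """20 strongly driven place cells, 5 untuned, ~30 laps."""
    cfg = high_snr_config(
        duration_s=300.0, n_neurons=25, frac_tuned=0.8, seed=101
    )
    return Session(cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
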