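"""Shared fixtures: small deterministic runs reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import repelsim as rs


@pytest.fixture(scope="session")
def small_attractant_run():
    """A short attractant-only experiment (5 replicates, calibrated defaults)."""
    cfg = rs.make_scenario("attractant_only", n_replicates=5, base_seed=11)
    return cfg, rs.run_experiment(cfg)


@pytest.fixture(scope="session")
def short_random_walk_run():
    """Source-free scenario truncated to 60 s: every mosquito is censored."""
    cfg = rs.make_scenario("random_walk", n_replicates=5, base_seed=7, max_duration=60.0)
    return cfg, rs.run_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
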