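"""Shared fixtures: one short simulated deployment reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from morus import simulate


@pytest.fixture(scope="session")
def short_deployment():
    """A 0.1-day deployment with a handful of dives (seed 7, bird 0)."""
    cfg = simulate.SimulationConfig(seed=7, deployment_days=0.1)
    return simulate.simulate_deployment(cfg, 0)


@pytest.fixture(scope="session")
def isotope_dataset():
    """Two-group, two-source synthetic isotope data with known proportions."""
    cfg = simulate.IsotopeSimConfig(seed=21)
    consumers, sources = simulate.simulate_isotopes(cfg)
    return cfg, consumers, sources


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
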