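"""Shared fixtures: small configurations and hand-placed particle states."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from eprsim.engine import (
    STATUS_ACTIVE,
    SimulationConfig,
    new_state,
)
from eprsim.geometry import classify_region_codes


@pytest.fixture
def config():
    """A small, fast default configuration (no EPR, always-on)."""
    return SimulationConfig(n_particles=200, max_frames=600, seed=7).validate()


def make_config(**overrides) -> SimulationConfig:
    base = dict(n_particles=200, max_frames=600, seed=7)
    base.update(overrides)
    return SimulationConfig(**base).validate()


def place_particles(config: SimulationConfig, positions, directions):
    """A state whose particles are all active at the given positions.

    ``config.n_particles`` must match the number of rows.  Directions are
    normalized; regions are classified from the positions.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    assert positions.shape == directions.shape == (config.n_particles, 3)
    state = new_state(config)
    state.status[:] = STATUS_ACTIVE
    state.positions[:] = positions
    state.directions[:] = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    state.region[:] = classify_region_codes(positions, config.geometry, config.epr_enabled)
    return state


@pytest.fixture
def make_cfg():
    return make_config


@pytest.fixture
def placed():
    return place_particles
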