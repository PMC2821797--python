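"""Shared fixtures: small head geometries reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from headpsf.geometry import (
    make_nested_head,
    make_shell_spec,
    place_electrodes,
)


@pytest.fixture(scope="session")
def shells():
    """Default four-shell spec: 92 mm scalp, published proportions."""
    return make_shell_spec()


@pytest.fixture(scope="session")
def sphere_head(shells):
    """Concentric-sphere head at a small vertex budget (fast)."""
    return make_nested_head(shells, 0.0, target_vertices=342)


@pytest.fixture(scope="session")
def sphere_head_medium(shells):
    """Concentric-sphere head at moderate resolution for solver oracles."""
    return make_nested_head(shells, 0.0, target_vertices=642)


@pytest.fixture(scope="session")
def electrodes(sphere_head):
    return place_electrodes(sphere_head[0], 62)


@pytest.fixture(scope="session")
def electrodes_medium(sphere_head_medium):
    return place_electrodes(sphere_head_medium[0], 62)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
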