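"""Shared fixtures.

The expensive end-to-end phantom runs are session-scoped so the placement
batch (4 scenarios x 3 cycles on the default 256x128 grid) is simulated once
and its metrics are shared by the acceptance assertions. A coarse phantom
configuration is provided for fast smoke-level runs.
"""

import numpy as np
import pytest

from ibvalve.phantom import PhantomConfig, make_phantom
from ibvalve.simulation import RunParams, run_placements


@pytest.fixture(scope="session")
def coarse_config():
    """Half-resolution phantom for fast functional runs (not the study grid)."""
    return PhantomConfig(nx=128, ny=64, h=1.0e-3)


@pytest.fixture()
def scene():
    return make_phantom()


@pytest.fixture(scope="session")
def placement_batch():
    """The study batch: four placements, three cycles each, default conditions."""
    results, failures = run_placements(params=RunParams(n_cycles=3))
    assert not failures, f"scenario failures: {failures}"
    return {r.label: r for r in results}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
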