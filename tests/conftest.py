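"""Shared fixtures: small synthetic sessions and ideal-map helpers.

Everything is generated programmatically with fixed seeds; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from gridvar.gridsim import GridCellParams, GridPopulationSpec, ideal_rate_map, make_synthetic_session
from gridvar.io_core import derive_rng
from gridvar.ratemaps import RateMap


ARENA = (150.0, 150.0)
N_BINS = 50
BIN_SIZE = ARENA[0] / N_BINS


def ideal_map(lam: float = 85.0, theta: float = 6.0, phase=(30.0, 55.0), xmax: float = 13.0) -> RateMap:
    """Noiseless rate map of one ideal grid cell on the standard 50x50 grid."""
    params = GridCellParams(lam, theta, phase, xmax)
    vals = ideal_rate_map(params, ARENA, N_BINS)
    return RateMap(
        values=vals,
        occupancy=np.ones_like(vals),
        bin_size=BIN_SIZE,
        visited_mask=np.ones_like(vals, dtype=bool),
    )


@pytest.fixture(scope="session")
def standard_ideal_map() -> RateMap:
    return ideal_map()


@pytest.fixture(scope="session")
def short_session():
    """A 10-minute, 4-cell synthetic session for structural tests."""
    spec = GridPopulationSpec(n=4)
    rec, truth = make_synthetic_session(spec, 600.0, derive_rng(42, 0), session_id="short")
    return rec, truth


@pytest.fixture(scope="session")
def long_single_cell_session():
    """A 130-minute single-cell session for estimation-accuracy tests."""
    spec = GridPopulationSpec(n=1, sigma_lambda=0.0, sigma_theta=0.0)
    rec, truth = make_synthetic_session(spec, 130 * 60.0, derive_rng(43, 0), session_id="long1")
    return rec, truth
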