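"""Shared fixtures.

Heavy simulation ensembles are session-scoped and shared between the
acceptance tests and the statistics tests so that the whole suite fits the
runtime budget.  All ensembles are fully seeded and deterministic.

The neutral ensemble uses a desk-scale well, 50 x 20 um with the (T, A) =
(10, 5) corrugation kept at full scale (pocket theory: 6 clones), and a
slightly coarser integration step than the default profile; the selection
ensembles use the shipped default profile.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from corrugo.biofilm_sim import desk_profile, initialize, run
from corrugo.well_geometry import WellSpec

settings.register_profile("suite", max_examples=30, deadline=None)
settings.load_profile("suite")

# neutral-ensemble geometry and duration
WIDTH = 50.0
HEIGHT = 20.0
N_INIT = 88
T_END = 88.0
ENSEMBLE_DT = 5e-4

# selection-ensemble geometry (matches scripts/acceptance.py target t3)
SEL_WIDTH = 40.0
SEL_HEIGHT = 20.0
SEL_N_INIT = 70


def corrugated_spec(width=WIDTH, height=HEIGHT) -> WellSpec:
    return WellSpec.corrugated(10.0, 5.0, width, height)


def flat_spec(width=WIDTH, height=HEIGHT) -> WellSpec:
    return WellSpec.flat_bottom(width, height)


def fast_params(**overrides):
    """Shipped default desk physics."""
    return desk_profile(**overrides)


def ensemble_params():
    """Desk physics with the coarser step used for the long neutral runs."""
    return desk_profile(dt=ENSEMBLE_DT)


@pytest.fixture(scope="session")
def neutral_ensemble():
    """Paired corrugated/flat neutral runs over matched seeds (t=0..88 h)."""
    seeds = list(range(10))
    out = {"seeds": seeds, "corrugated": [], "flat": []}
    for seed in seeds:
        out["corrugated"].append(
            run(corrugated_spec(), ensemble_params(), t_end=T_END,
                snapshot_every=4.0, n_cells=N_INIT, seed=seed)
        )
        out["flat"].append(
            run(flat_spec(), ensemble_params(), t_end=T_END,
                snapshot_every=4.0, n_cells=N_INIT, seed=seed)
        )
    return out


@pytest.fixture(scope="session")
def flat_run(neutral_ensemble):
    """One representative flat-well run (snapshots every 4 h)."""
    return neutral_ensemble["flat"][0]


@pytest.fixture(scope="session")
def small_state():
    """A tiny relaxed population for cheap unit tests."""
    state = initialize(flat_spec(), fast_params(), 12, {"neutralA": 1.0}, seed=7)
    return state
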