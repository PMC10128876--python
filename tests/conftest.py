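import numpy as np
import pandas as pd
import pytest

from stimconn import SyntheticConfig, generate_cohort
from stimconn.tracts import streamlines_touching
from stimconn.volumes import Grid, VAT


@pytest.fixture(scope="session")
def cohort():
    """One reference synthetic cohort shared across the suite."""
    return generate_cohort(SyntheticConfig(rng_seed=1))


@pytest.fixture(scope="session")
def connected_sets(cohort):
    """Per-subject sets of fibre ids touched by the bilateral VAT seed."""
    return {
        s: streamlines_touching(
            cohort.vats[s]["left"].union(cohort.vats[s]["right"]),
            cohort.tractogram,
        )
        for s in cohort.config.subjects
    }


@pytest.fixture
def grid():
    return Grid(shape=(20, 20, 20))


def make_vat(grid, voxels, hemisphere=""):
    mask = np.zeros(grid.shape, dtype=bool)
    for v in voxels:
        mask[tuple(v)] = True
    return VAT(mask=mask, grid=grid, hemisphere=hemisphere)


def make_trials(rows):
    """Trial table from (subject, condition, target, direction, latency)."""
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "condition",
            "target_side",
            "first_saccade_direction",
            "latency_ms",
        ],
    )
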