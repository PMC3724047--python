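"""Shared fixtures: a desk-scale scenario and a simulated subject."""

import numpy as np
import pytest

import dmndyn as dd
from dmndyn.scenario import PlantedRegion, _cube


def small_scenario(**overrides):
    """A reduced four-state study for fast unit tests.

    Seven regions (three stable including the seed-bearing one, two
    decreasing, two increasing) on a 22x26x22 grid, 80 volumes.
    """
    layout = [
        PlantedRegion("PCC", "stable", _cube((11, 6, 11), 2), 0),
        PlantedRegion("MPFC", "stable", _cube((11, 21, 11), 1), 1),
        PlantedRegion("LTC_L", "stable", _cube((4, 13, 8), 1), 2),
        PlantedRegion("PCS", "decreasing", _cube((11, 4, 18), 1), 3),
        PlantedRegion("ANG_R", "decreasing", _cube((18, 4, 13), 1), 4),
        PlantedRegion("ACC", "increasing", _cube((11, 14, 16), 1), 5),
        PlantedRegion("IIFC_L", "increasing", _cube((4, 20, 14), 1), 6),
    ]
    systems = [r.system for r in layout]
    base = dict(
        grid_shape=(22, 26, 22),
        n_subjects=6,
        n_volumes=80,
        region_layout=layout,
        state_covariance=dd.scenario.block_correlation_matrices(systems),
        # places the default seed center (0, -53, 26) at voxel (11, 6, 11),
        # the middle of the small PCC cube
        origin_mm=(-33.0, -71.0, -7.0),
    )
    base.update(overrides)
    return dd.default_scenario(**base)


@pytest.fixture(scope="session")
def tiny_scenario():
    return small_scenario()


@pytest.fixture(scope="session")
def tiny_subject(tiny_scenario):
    return dd.simulate_subject(tiny_scenario, 0, np.random.SeedSequence(7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
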