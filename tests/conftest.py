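import numpy as np
import pytest

import reefplan as rp
from reefplan.tessellation import PUStatus


def chain_tessellation(n: int, side: float = 15.0) -> rp.Tessellation:
    """A hand-checkable instance: n hexagons in a single adjacent row."""
    dy = np.sqrt(3.0) * side
    units = [
        rp.PlanningUnit(
            id=i + 1,
            centroid=(10.0, 10.0 + i * dy),
            area=rp.hexagon_area(side) / rp.M2_PER_HA,
            cost=1.0,
        )
        for i in range(n)
    ]
    adjacency = {(i, i + 1): side for i in range(1, n)}
    return rp.Tessellation(
        units=units, extent=(40.0, 10.0 + n * dy), side=side, adjacency=adjacency
    )


def random_instance(seed: int, extent=(80.0, 80.0), n_lockout: int = 2):
    """A seeded random small geometric instance (14 PUs on an 80 m square)."""
    rng = np.random.default_rng(seed)
    tess = rp.build_hex_tessellation(extent, 15.0)
    n = len(tess)
    for u in tess.units:
        u.cost = float(rng.integers(0, 4))
    amounts = {
        pu: float(rng.uniform(0.0, tess.pu_area_ha))
        for pu in range(1, n + 1)
        if rng.random() < 0.5
    }
    features = rp.FeatureTable(
        features=[rp.Feature(1, "habitat", float(sum(amounts.values())))],
        amounts={1: amounts},
    )
    for i in rng.choice(n, size=n_lockout, replace=False):
        tess.units[i].status = PUStatus.LOCKOUT
    scenario = rp.ScenarioConfig(
        target_fraction=0.4,
        blm=float(rng.choice([0.0, 0.01, 0.1])),
        spf=20.0,
        n_runs=1,
        iterations_per_run=10_000,
        rng_seed=seed,
    )
    return tess, features, scenario


@pytest.fixture(scope="session")
def test_seascape():
    """The ~1,500-PU test-profile seascape shared across tests."""
    spec = rp.SeascapeSpec.test_profile(rng_seed=11)
    tess, features = rp.build_seascape(spec)
    return spec, tess, features


@pytest.fixture(scope="session")
def mini_seascape():
    """A ~190-PU seascape for fast end-to-end checks."""
    spec = rp.SeascapeSpec.scaled(0.02, rng_seed=3)
    tess, features = rp.build_seascape(spec)
    return spec, tess, features
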