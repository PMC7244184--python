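import numpy as np
import pytest

from adaptivecrm import (
    CommunityParams,
    CommunityState,
    ResourceParams,
    SpeciesParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_by_two():
    """Small handcrafted adaptive community: 2 species, 2 resources."""
    species = [
        SpeciesParams(death_rate=0.1, ctr=2.0, learning_rate=0.2),
        SpeciesParams(death_rate=0.2, ctr=1.5, learning_rate=0.4),
    ]
    resources = [
        ResourceParams(value=1.5, half_saturation=1.0, supply=100.0),
        ResourceParams(value=1.0, half_saturation=0.8, supply=50.0),
    ]
    params = CommunityParams(species, resources, adaptive=True)
    state = CommunityState(
        n=[1e4, 2e4],
        c=[1.0, 0.5],
        A=[[0.05, 0.05], [0.08, 0.04]],
    )
    return params, state


def random_community(rng, m=3, p=2, adaptive=True, lam_scale=0.1):
    """Random valid community used by property tests."""
    species = [
        SpeciesParams(
            death_rate=rng.uniform(0.05, 0.5),
            ctr=rng.uniform(1.0, 3.0),
            learning_rate=lam_scale * rng.uniform(0.5, 2.0),
        )
        for _ in range(m)
    ]
    resources = [
        ResourceParams(
            value=rng.uniform(0.5, 2.0),
            half_saturation=rng.uniform(0.5, 1.5),
            supply=rng.uniform(10.0, 200.0),
            degradation=rng.uniform(0.0, 0.1),
        )
        for _ in range(p)
    ]
    params = CommunityParams(species, resources, adaptive=adaptive)
    A = rng.dirichlet(np.ones(p), size=m)
    A *= (rng.uniform(0.3, 1.0, m) * params.e_star / A.sum(axis=1))[:, None]
    state = CommunityState(
        n=rng.uniform(1e2, 1e4, m),
        c=rng.uniform(0.1, 2.0, p),
        A=A,
    )
    return params, state
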