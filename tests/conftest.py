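import numpy as np
import pytest
from hypothesis import settings

import genident as gi

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tracked_run():
    """Small fully tracked simulation (pedigree + ancestry) reused across tests."""
    cfg = gi.ScenarioConfig(n0=60, generations=8, x0=0.2, alpha=0.5, seed=7,
                            track_pedigree=True, track_ancestry=True)
    return gi.simulate(cfg)


def walk_ancestors(pedigree, t, i):
    """Reference recursive founder-ancestor enumeration (plain python sets)."""
    if t == 0:
        return {i}
    layer = pedigree[t - 1]
    return (walk_ancestors(pedigree, t - 1, int(layer.parent1[i]))
            | walk_ancestors(pedigree, t - 1, int(layer.parent2[i])))
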