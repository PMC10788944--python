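import numpy as np
import pytest

import degradertcm as d


@pytest.fixture(scope="session")
def clean_system():
    """One clean toy system: halves, truth, and the merged (unrefined) model."""
    poi, e3, truth = d.make_toy_tc(d.FixtureSpec(seed=3))
    tc = d.superpose_and_merge(d.minimize_half(poi), d.minimize_half(e3))
    return {"poi": poi, "e3": e3, "truth": truth, "tc": tc}


@pytest.fixture(scope="session")
def refined_system(clean_system):
    """The clean system taken through the full staged refinement."""
    refined, report = d.refine(clean_system["tc"].copy())
    return {**clean_system, "refined": refined, "report": report}


@pytest.fixture(scope="session")
def clashed_tc():
    """A merged model carrying one injected side-chain clash."""
    poi, e3, _ = d.make_toy_tc(d.FixtureSpec(seed=5, flavor="CLASHED"))
    return d.superpose_and_merge(poi, e3)


def random_points(rng, n, spread=5.0):
    pts = rng.normal(scale=spread, size=(n, 3))
    # reject (near-)degenerate cloud
    while np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)[1] < 0.5:
        pts = rng.normal(scale=spread, size=(n, 3))
    return pts


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
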