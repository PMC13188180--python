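import numpy as np
import pytest

import topovox as tv


@pytest.fixture(scope="session")
def worked_grid():
    """2D integer grid realizing the canonical worked sublevel filtration.

    Four mutually non-adjacent value-1 regions (one a one-pixel-thick ring
    enclosing a value-4 pixel), value-3 pixels bridging exactly two regions,
    one value-2 pixel touching a region without changing topology, all else
    value 5.  Regions are separated by >= 2 pixels so the expected events do
    not depend on the diagonal-connectivity convention.

    Expected events: four H0 classes born at t=1 (one dying at 3 via the
    bridge, two at 5, one essential); one H1 class born 1, dead 4 when the
    enclosed pixel activates.
    """
    g = np.full((9, 11), 5, dtype=float)
    g[1, 1] = 1                       # region A
    g[0, 1] = 2                       # joins A at t=2, no topology change
    g[2, 1] = g[3, 1] = g[4, 1] = 3   # bridge A <-> C at t=3
    g[5, 1] = 1                       # region C
    g[1:4, 5:8] = 1                   # region B: 3x3 ring ...
    g[2, 6] = 4                       # ... enclosing one late pixel
    g[7, 5] = 1                       # region D
    return g


@pytest.fixture(scope="session")
def shell_grid():
    """Hollow-sphere phantom: one component enclosing one cavity."""
    grid, betti = tv.make_phantom(
        tv.PhantomSpec(shape=(14, 14, 14), n_blobs=0, n_shells=1, seed=3)
    )
    assert betti == (1, 0, 1)
    return grid


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-class tabular cohort with one strongly informative feature."""
    rng = np.random.default_rng(7)
    n = 60
    import pandas as pd
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 30))
    X[:, 0] += 2.5 * y
    cols = [f"landscape_d2_l0_b{i}" for i in range(15)] + \
           [f"betti_d1_b{i}" for i in range(15)]
    df = pd.DataFrame(X, columns=cols,
                      index=[f"s{i:02d}" for i in range(n)])
    df["label"] = y
    return df
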