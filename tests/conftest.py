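import numpy as np
import pytest
from hypothesis import settings

from nichedyn import simulate as sim

settings.register_profile("deterministic", derandomize=True,
                          database=None, deadline=None)
settings.load_profile("deterministic")


import zlib


@pytest.fixture()
def rng(request):
    # a fresh, order-independent stream per test, seeded from the test name
    seed = zlib.crc32(request.node.name.encode()) % 2**31
    return np.random.default_rng([12345, seed])


@pytest.fixture(scope="session")
def driver_table():
    """One synthetic species-by-realm driver table (n=337, known effects)."""
    return sim.generate_driver_table(seed=3)


@pytest.fixture(scope="session")
def small_scenario():
    """A small conserved-niche scenario shared across tests."""
    return sim.make_scenario(n_native=300, n_alien=300, n_cells=10000, seed=11)


def toy_grid(z, background=None, edges=None):
    """Hand-built occupancy grid on unit cells (strict-positivity support)."""
    from nichedyn.ordination import OccupancyGrid

    z = np.asarray(z, dtype=float)
    R1, R2 = z.shape
    if edges is None:
        e1 = np.arange(R1 + 1, dtype=float)
        e2 = np.arange(R2 + 1, dtype=float)
    else:
        e1, e2 = edges
    if background is None:
        background = np.ones_like(z)
    return OccupancyGrid(
        edges1=e1, edges2=e2, z=z,
        background=np.asarray(background, dtype=float), corrected=False,
    )
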