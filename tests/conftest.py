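import numpy as np
import pytest

from rnaswim.map_io import DensityMap
from rnaswim.synthetic import FixtureSpec, make_fixture, render_synthetic_maps
from rnaswim.swim import run_swim


@pytest.fixture(scope="session")
def fixture():
    """Standard high-SNR fixture: 12-bp duplex, 12 waters, 2 Mg2+."""
    return make_fixture(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def swim_placements(fixture):
    """SWIM run on the standard fixture (shared across tests)."""
    return run_swim(fixture["full"], fixture["half1"], fixture["half2"],
                    fixture["model"])


@pytest.fixture(scope="session")
def second_map_pair(fixture):
    """Independent-noise re-render of the same solvated model."""
    return render_synthetic_maps(fixture["solvated"], 2.2, 0.02, seed=99)


@pytest.fixture(scope="session")
def swim_placements_b(fixture, second_map_pair):
    full_b, h1_b, h2_b = second_map_pair
    return run_swim(full_b, h1_b, h2_b, fixture["model"])


def gaussian_map(center, sigma=0.6, voxel=0.3, n=41, origin=(0.0, 0.0, 0.0),
                 amplitude=1.0):
    """Single isotropic Gaussian sampled on a cubic grid."""
    origin = np.asarray(origin, dtype=float)
    ax = [origin[i] + np.arange(n) * voxel for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    c = np.asarray(center, dtype=float)
    r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
    return DensityMap(amplitude * np.exp(-r2 / (2 * sigma ** 2)),
                      voxel, origin)
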