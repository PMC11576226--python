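import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from neurofcd.io_volumes import BoldSeries, Mask, VolumeGrid
from neurofcd.synthetic import HubSpec, LongRangePair, SyntheticConfig


@pytest.fixture
def small_grid():
    return VolumeGrid((6, 6, 6), (2.0, 2.0, 2.0))


@pytest.fixture
def full_mask(small_grid):
    return Mask(small_grid, np.ones(small_grid.shape, dtype=bool))


def make_two_block_bold(seed: int = 5, n_timepoints: int = 120) -> BoldSeries:
    """Two noiseless 2x2x2 blocks at opposite corners of a 6x6x6 grid sharing
    one latent series; independent white noise elsewhere."""
    rng = np.random.default_rng(seed)
    grid = VolumeGrid((6, 6, 6), (2.0, 2.0, 2.0))
    data = rng.standard_normal((6, 6, 6, n_timepoints))
    latent = rng.standard_normal(n_timepoints)
    data[0:2, 0:2, 0:2, :] = latent
    data[4:6, 4:6, 4:6, :] = latent
    return BoldSeries(grid, data, sampling_interval_s=2.5)


@pytest.fixture
def two_block_bold():
    return make_two_block_bold()


@pytest.fixture
def block_voxels():
    a = [(i, j, k) for i in range(2) for j in range(2) for k in range(2)]
    b = [(i, j, k) for i in range(4, 6) for j in range(4, 6) for k in range(4, 6)]
    return a, b


def make_random_hub_config(seed: int, n_timepoints: int = 60) -> SyntheticConfig:
    """A randomized small study volume: 6x6x6 grid with 2 hubs and one
    long-range pair at random positions and correlation levels."""
    rng = np.random.default_rng(seed)
    while True:
        centers = [tuple(int(c) for c in rng.integers(1, 5, 3)) for _ in range(2)]
        if max(abs(a - b) for a, b in zip(*centers)) > 2:
            break
    rho_ws = rng.uniform(0.65, 0.95, 2)
    hubs = tuple(HubSpec(center=c, radius=1.0, within_correlation=float(r))
                 for c, r in zip(centers, rho_ws))
    rho_b = float(rng.uniform(0.3, rho_ws.min()))
    return SyntheticConfig(
        grid_shape=(6, 6, 6),
        n_timepoints=n_timepoints,
        hubs=hubs,
        long_range=(LongRangePair(0, 1, rho_b),),
        seed=int(seed),
    )
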