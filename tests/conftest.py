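import numpy as np
import pytest

from neonoci.images import VoxelMap
from neonoci.simulate import PhantomGeometry, default_event_schedule, gen_templates


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry((12, 12, 8))


@pytest.fixture(scope="session")
def templates(geometry):
    return gen_templates(geometry, k_rsn=3, adult_target_corrs=[1.0, 0.0, 0.5],
                         seed=11)


@pytest.fixture(scope="session")
def group_map(templates):
    return templates["group_map"]


@pytest.fixture
def events():
    return default_event_schedule(n_events=4, first_onset_s=5.0, isi_s=26.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def random_map(rng, geometry):
    data = rng.normal(size=geometry.grid_shape)
    return VoxelMap(data, geometry.mask.copy(), tuple(geometry.voxel_size_mm))
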