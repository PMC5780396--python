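import numpy as np
import pytest

from bspim import AcquisitionConfig, GridGeometry, make_scene, simulate_scan

# Small study geometry used across tests: a 2.5 mm-wide field sampled at the
# cuvette scale, 12 sheet positions deep.
TINY_GEOMETRY = GridGeometry(grid_shape=(64, 64, 12), voxel_size_xy=39.0625, z_step=125.0)
TINY_ACQ = AcquisitionConfig(frames_per_position=16, n_positions=12)

# A medium field large enough for several well-separated animals.
SMALL_GEOMETRY = GridGeometry(grid_shape=(128, 128, 24), voxel_size_xy=39.0625, z_step=125.0)
SMALL_ACQ = AcquisitionConfig(frames_per_position=32, n_positions=24)


def small_scene(n, seed=5, alive_fraction=1.0, **kw):
    kw.setdefault("length_range_um", (200.0, 500.0))
    kw.setdefault("z_margin_um", 600.0)
    return make_scene(
        n, alive_fraction=alive_fraction, geometry=SMALL_GEOMETRY, seed=seed, **kw
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_scan():
    """A 2-nematode scan at reduced size, shared where content is irrelevant."""
    scene = make_scene(
        2,
        geometry=TINY_GEOMETRY,
        seed=7,
        length_range_um=(200.0, 400.0),
        z_margin_um=500.0,
    )
    return simulate_scan(scene, TINY_ACQ)
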