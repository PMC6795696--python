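import numpy as np
import pytest

from habitatmap.phantom import PhantomSpec, generate_phantom, place_training_rois
from habitatmap.training_data import assemble_training_set, synthesize_novelty_rois
from habitatmap.volumes_io import ParameterVolume, Quantity, VoxelGrid


@pytest.fixture(scope="session")
def default_phantom():
    """The default 64x64x16 phantom, seeded."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def phantom_training(default_phantom):
    """CV training set from the default phantom: 2 image ROIs per tissue
    class plus the 15 synthesized novelty ROIs."""
    rois = place_training_rois(default_phantom, n_per_class=2, seed=7)
    novelty = synthesize_novelty_rois(seed=7)
    cv_set, _ = assemble_training_set(rois, novelty, [])
    return cv_set


@pytest.fixture
def small_grid():
    return VoxelGrid(shape=(4, 4, 2), spacing=(1.5, 1.5, 3.0))


def make_volume(values, quantity=Quantity.SIGNAL, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    grid = VoxelGrid(shape=values.shape, spacing=spacing)
    return ParameterVolume(grid=grid, values=values, quantity=quantity)


@pytest.fixture
def volume_factory():
    return make_volume
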