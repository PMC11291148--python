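import numpy as np
import pytest
import trimesh

from morphrep.synth import (
    PackingRuleSpec,
    PolymorphicShapeSpec,
    make_multipiece_volume,
    make_synthetic_nucleus,
    pack_spheres,
)


def random_rotation(seed: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=seed).as_matrix()


@pytest.fixture(scope="session")
def nucleus():
    return make_synthetic_nucleus(seed=0)


@pytest.fixture(scope="session")
def small_pack(nucleus):
    return pack_spheres(nucleus, PackingRuleSpec(rule="random", n_spheres=64, seed=1))


@pytest.fixture(scope="session")
def multipiece():
    return make_multipiece_volume(PolymorphicShapeSpec(n_pieces=3, seed=7))


@pytest.fixture(scope="session")
def unit_box_mesh():
    return trimesh.creation.box(extents=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def sphere_mesh():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """24 clouds (4 nuclei x 6 rules), 64 points each."""
    from morphrep.synth import generate_rule_dataset

    return generate_rule_dataset(n_nuclei=4, n_spheres=64, seed=0)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A briefly trained small folding autoencoder shared across tests."""
    from morphrep.nn import ModelConfig, TrainConfig, train_autoencoder

    cfg = ModelConfig.punctate(
        latent_dim=16, hidden_dim=16, n_blocks=3, template_points=64, seed=0
    )
    tcfg = TrainConfig(epochs=2, lr=1e-3, batch_size=8, loss="chamfer", seed=0)
    model, history = train_autoencoder(tiny_dataset, cfg, tcfg)
    return model, history
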