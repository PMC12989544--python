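import numpy as np
import pytest

from teabud3d import SceneSpec, SemanticPointCloud, dsc_filter, generate_tree


@pytest.fixture(scope="session")
def clean_scene():
    """Small clean 5-bud scene: no dropout, no noise; shared across tests."""
    spec = SceneSpec(n_buds=5, seed=3, occlusion_dropout=0.0, noise_sd=0.0)
    cloud, truth = generate_tree(spec)
    return spec, cloud, truth


@pytest.fixture(scope="session")
def clean_bud_cloud(clean_scene):
    _, cloud, _ = clean_scene
    _, buds = dsc_filter(cloud)
    return buds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cloud(rng, n, scale=1.0):
    """Uniform random test cloud with neutral density/probability channels."""
    return SemanticPointCloud(
        positions=rng.uniform(-scale, scale, (n, 3)),
        density=np.ones(n),
        bud_prob=np.zeros(n),
    )
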