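import pytest

from e3prio.pipeline import build_atlas
from e3prio.simulate import SimConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default-scale synthetic bundle with 5 planted preset passers."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(seed=11, n_case1_passers=5)
    path, manifest = generate_bundle(cfg, out)
    return path, manifest


@pytest.fixture(scope="session")
def bundle_dir(bundle):
    return bundle[0]


@pytest.fixture(scope="session")
def manifest(bundle):
    return bundle[1]


@pytest.fixture(scope="session")
def atlas(bundle_dir):
    return build_atlas(bundle_dir)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small bundle config for tests that regenerate bundles repeatedly."""
    return SimConfig(
        seed=5, n_ligases=30, n_targets=160, n_tumor_types=4,
        n_normal_tissues=5, samples_per_tissue=6, cells_per_tissue=48,
        tumor_cells=150, n_case1_passers=3, n_co_opted=3, n_clinical=1,
    )
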