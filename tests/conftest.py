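import numpy as np
import pytest
from hypothesis import settings

from dentexture import SyntheticProfile, generate_dataset
from dentexture.pipeline import load_manifest

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def benchmark_dir(tmp_path_factory):
    """The default 600-image synthetic benchmark, generated once per session."""
    root = tmp_path_factory.mktemp("benchmark")
    generate_dataset(SyntheticProfile(seed=7), root)
    return root


@pytest.fixture(scope="session")
def benchmark_manifest(benchmark_dir):
    return load_manifest(benchmark_dir)


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory):
    """A reduced benchmark (8 images per class) for fast integration tests."""
    root = tmp_path_factory.mktemp("small")
    generate_dataset(SyntheticProfile(class_counts=(8,) * 9, seed=11), root)
    return root


@pytest.fixture
def rng():
    return np.random.default_rng(42)
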