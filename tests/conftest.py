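import pytest

from anispecies.config import Config
from anispecies.synthetic import SyntheticSpec, generate_dataset, dataset_release


@pytest.fixture
def config():
    return Config()

@pytest.fixture
def separable_dataset():
    """Planted-partition dataset with a clean gap around the 95% radius."""
    return generate_dataset(SyntheticSpec(n_species=8, genomes_per_species=(2, 6)), seed=11)


@pytest.fixture
def separable_release(separable_dataset):
    return dataset_release(separable_dataset)
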