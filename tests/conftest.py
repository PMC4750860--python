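import numpy as np
import pytest

from exopair.synthetic_data import (SimConfig, generate_annotations,
                                    plant_sites, simulate_exo_tags)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_chroms=1, chrom_length=300_000, n_genes=30, n_trna=8,
                     divergent_fraction=0.5, background_rate=0.5, seed=11)


@pytest.fixture(scope="session")
def small_genome(small_config):
    annotations = generate_annotations(small_config)
    truth = plant_sites(annotations, small_config)
    return annotations, truth


@pytest.fixture(scope="session")
def tfiib_tags(small_config, small_genome):
    _, truth = small_genome
    return simulate_exo_tags(truth, small_config, factor="TFIIB")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
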