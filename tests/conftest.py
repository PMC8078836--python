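import numpy as np
import pytest

from mdassoc import (
    GeneratorConfig,
    MDADataset,
    MetaboliteDiseaseModel,
    ModelConfig,
    generate,
    tiny_fixture,
)


@pytest.fixture(scope="session")
def tiny():
    """Hand-checkable 4-disease x 6-metabolite dataset."""
    m, mp, catalog = tiny_fixture()
    return m, mp, catalog


@pytest.fixture(scope="session")
def tiny_dataset(tiny):
    return MDADataset(*tiny)


@pytest.fixture(scope="session")
def fast_config():
    """Small classifier/feature settings for quick protocol tests."""
    return ModelConfig(
        n_estimators=40,
        min_data_in_leaf=5,
        nmf_rank=4,
        nmf_max_iter=100,
    )


@pytest.fixture(scope="session")
def small_planted():
    """A small planted-block instance with strong signal (fast to cross-validate)."""
    cfg = GeneratorConfig(
        n_diseases=12,
        n_metabolites=30,
        n_pathways=10,
        n_symptoms=12,
        n_blocks=3,
        within_block_assoc_prob=0.5,
        background_assoc_prob=0.02,
        seed=11,
    )
    m, mp, catalog, ledger = generate(cfg)
    return m, mp, catalog, ledger


@pytest.fixture(scope="session")
def small_model(small_planted, fast_config):
    m, mp, catalog, _ = small_planted
    return MetaboliteDiseaseModel(MDADataset(m, mp, catalog), fast_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
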