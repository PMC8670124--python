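import numpy as np
import pytest
from hypothesis import settings

from flimma.data_model import AnalysisConfig
from flimma.synthetic_data import SimulationSpec, generate_dataset, split_cohorts

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """400 genes x 48 samples, 10% DE at |log2FC| = 2, fixed seed."""
    spec = SimulationSpec(n_genes=400, n_samples=48, seed=11)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_cohorts(small_dataset):
    cm, dm, truth = small_dataset
    return split_cohorts(cm, dm, truth, [1, 1, 1], seed=11)


@pytest.fixture()
def config():
    return AnalysisConfig(coefficient="group", seed=3)


@pytest.fixture()
def config_unmasked():
    return AnalysisConfig(coefficient="group", seed=3, masking=False)


def random_counts(rng: np.random.Generator, n_genes: int, n_samples: int) -> np.ndarray:
    """Toy count matrix with a spread of expression levels."""
    base = rng.uniform(0, 8, size=n_genes)
    mu = 2.0 ** base[:, None] * rng.uniform(0.5, 2.0, size=(n_genes, n_samples))
    return rng.poisson(mu).astype(np.int64)
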