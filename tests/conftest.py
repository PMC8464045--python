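import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spartan

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def planted_instance():
    """A planted bilinear cohort at the generator's default conditions."""
    return spartan.generate_instance(spartan.SimConfig(seed=1))


@pytest.fixture(scope="session")
def planted_training(planted_instance):
    """Aligned, unit-normalized (Y, P, D) from the planted cohort."""
    return spartan.latent_training_data(planted_instance)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def small_counts(matrix, modality="rna", prefix="g"):
    """Build RawCounts around a dense integer matrix with generated ids."""
    matrix = np.asarray(matrix)
    feats = [f"{prefix}{i}" for i in range(matrix.shape[0])]
    cells = [f"c{j}" for j in range(matrix.shape[1])]
    return spartan.RawCounts(matrix, feats, cells, modality)
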