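import numpy as np
import pytest

from pgsubtype import gaae
from pgsubtype.cohort import CohortSpec, generate_cohort
from pgsubtype.graph import build_population_graph


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_id=60, n_hc=25, n_roi=30, n_skeleton=40,
                      subtype_fractions=(0.6, 0.4), seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_graph(small_cohort):
    return build_population_graph(small_cohort)


@pytest.fixture(scope="session")
def trained_small(small_graph):
    """One trained model reused across tests that only inspect its outputs."""
    model, z, report = gaae.train(
        small_graph, cfg=gaae.TrainConfig(epochs=80, lambda_struct=0.3, seed=0))
    return model, z, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
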