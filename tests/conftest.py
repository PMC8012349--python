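import warnings

import pytest

from flavoromics import ingest, sensory
from flavoromics.simulate import (
    SimConfig,
    generate_chemical_matrix,
    generate_sensory_panel,
    make_truth,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Compact study: quick to generate but with the full structure."""
    return SimConfig(
        n_samples=60,
        n_panelists_per_session=25,
        n_volatiles=40,
        n_common_volatiles=24,
        n_enhancers=2,
        n_latent_pathways=5,
        n_markers=20,
        n_genotyped=150,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_truth(small_config)


@pytest.fixture(scope="session")
def small_chem(small_config, small_truth):
    return generate_chemical_matrix(small_config, small_truth)


@pytest.fixture(scope="session")
def small_ratings(small_config, small_truth):
    return generate_sensory_panel(small_config, small_truth)


@pytest.fixture(scope="session")
def small_scaled(small_chem):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ingest.autoscale_by_period(small_chem, log_transform=True)


@pytest.fixture(scope="session")
def small_means(small_ratings):
    return sensory.fit_panelist_adjusted_means(small_ratings)
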