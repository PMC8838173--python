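import numpy as np
import pytest

from dieteval import (
    ErrorModel,
    StudyConfig,
    generate_reference,
    load_fixture_composition,
    load_fixture_taxonomy,
    simulate_app,
)


@pytest.fixture(scope="session")
def tax():
    return load_fixture_taxonomy()


@pytest.fixture(scope="session")
def composition():
    return load_fixture_composition()


@pytest.fixture(scope="session")
def small_study(tax, composition):
    """One seeded default-size synthetic study with its simulated tool output."""
    cfg = StudyConfig(seed=11)
    ref = generate_reference(cfg, tax, composition)
    app, links = simulate_app(ref, ErrorModel(), tax, composition, seed=12)
    return ref, app, links


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
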