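import numpy as np
import pytest

import phenosom as ps


@pytest.fixture(scope="session")
def paper_table():
    """Paper-like synthetic population: 482 plots, 3 planted clusters."""
    return ps.generate_population(ps.preset_config("paper-like", seed=0))


@pytest.fixture(scope="session")
def encoded(paper_table):
    return ps.expand_dummies(paper_table)


@pytest.fixture(scope="session")
def layers(encoded):
    return ps.build_layers(encoded)


@pytest.fixture(scope="session")
def trained_model(encoded, layers):
    """Default 15x7/5000-iteration SOM on the paper-like population."""
    return ps.train_som(encoded, ps.SOMConfig(seed=0), layers)


@pytest.fixture(scope="session")
def small_table():
    """Small population for cheap end-to-end stages."""
    cfg = ps.preset_config("paper-like", seed=7, n_plots=90)
    return ps.generate_population(cfg)


def random_encoded(n, p_numeric, rng):
    """Numeric-only EncodedMatrix helper for SOM unit tests."""
    X = rng.normal(size=(n, p_numeric))
    return ps.EncodedMatrix(
        values=X,
        feature_names=[f"Zf{j}" for j in range(p_numeric)],
        sources=[f"f{j}" for j in range(p_numeric)],
        kinds=["numeric"] * p_numeric,
    )
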