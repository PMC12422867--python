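import numpy as np
import pytest

from hybriddiag import simulate


@pytest.fixture(scope="session")
def panel():
    """Small diverged species pair with known fixed-difference truth."""
    return simulate.simulate_species_pair(
        L=5000, divergence=0.05, polymorphism=0.002, seed=42
    )


@pytest.fixture(scope="session")
def clean_panel():
    """Diverged pair with no within-lineage polymorphism (error-free oracles)."""
    return simulate.simulate_species_pair(L=5000, divergence=0.05, seed=43)


@pytest.fixture(scope="session")
def f1(clean_panel):
    return simulate.simulate_cross(clean_panel, "F1", seed=7, sample_id="F1_test")


@pytest.fixture(scope="session")
def p1(clean_panel):
    return simulate.simulate_cross(clean_panel, "P1", seed=8, sample_id="P1_test")


@pytest.fixture(scope="session")
def p2(clean_panel):
    return simulate.simulate_cross(clean_panel, "P2", seed=9, sample_id="P2_test")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
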