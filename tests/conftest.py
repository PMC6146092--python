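import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kappaseq.caller import VAligner
from kappaseq.simulate import SimConfig, make_synthetic_locus

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_ref():
    """20-gene synthetic locus with two 3'-identical gene pairs."""
    return make_synthetic_locus(n_genes=20, seed=11, n_identical_pairs=2)


@pytest.fixture(scope="session")
def toy_aligner(toy_ref):
    return VAligner(toy_ref)


@pytest.fixture(scope="session")
def pairless_ref():
    """Locus without identical pairs (unambiguous V assignment)."""
    return make_synthetic_locus(n_genes=12, seed=7, n_identical_pairs=0)


@pytest.fixture(scope="session")
def pairless_aligner(pairless_ref):
    return VAligner(pairless_ref)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def clean_config(**kw) -> SimConfig:
    """Error-free, duplicate-free baseline config for oracle tests."""
    defaults = dict(
        n_molecules=1000, pcr_dup_rate=0.0, cross_prime_rate=0.0,
        seq_error_rate=0.0, jk_dirichlet_conc=None, inactive_frac=0.0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)
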