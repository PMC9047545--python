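import numpy as np
import pytest

from tmijoint.synth_fixtures import SynthSpec, make_mixtures, make_signature


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_mixture():
    """200-gene, 5-type, 20-sample noiseless mixture with known fractions."""
    spec = SynthSpec(seed=1, n_genes=200, m_cell_types=5, L_samples=20, noise_sd=0.0)
    S = make_signature(spec)
    X, truth = make_mixtures(S, spec)
    return S, X, truth


@pytest.fixture(scope="session")
def noisy_mixture():
    spec = SynthSpec(seed=1, n_genes=200, m_cell_types=5, L_samples=20, noise_sd=0.05)
    S = make_signature(spec)
    X, truth = make_mixtures(S, spec)
    return S, X, truth
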