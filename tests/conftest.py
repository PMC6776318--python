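import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_region(rng):
    """A small filtered genotype matrix with causal flags, n=60."""
    import rareqtl as rq

    freqs = rq.simulate_site_frequencies(30, 1e-3, 0.1, seed=1)
    G = rq.sample_genotypes(freqs, 60, seed=2)
    G = rq.assign_causal(G, 0.5, 0.05, seed=3)
    return rq.filter_common(G, 0.05)
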