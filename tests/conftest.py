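import numpy as np
import pytest

from genrescue import GenomeSpec, IdSource, draw_founding_frequencies, initialize_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A 40-locus genome keeping all three locus classes."""
    return GenomeSpec(n_neutral=20, n_migrant=10, n_conserved=10)


@pytest.fixture
def small_population(small_spec, rng):
    """A 60-individual recipient population on the small genome."""
    freqs = draw_founding_frequencies(small_spec, rng)
    return initialize_population(small_spec, "recipient", 60, freqs.recipient, rng, IdSource())


@pytest.fixture
def population_pair(small_spec, rng):
    """Recipient and source populations sharing one id space."""
    ids = IdSource()
    freqs = draw_founding_frequencies(small_spec, rng)
    recipient = initialize_population(
        small_spec, "recipient", 40, freqs.recipient, rng, ids
    )
    source = initialize_population(small_spec, "source", 80, freqs.source, rng, ids)
    return recipient, source
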