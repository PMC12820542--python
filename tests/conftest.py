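import pytest

from metaweight import load_path_counts, load_pe_bi_effects, records_from_counts


@pytest.fixture(scope="session")
def pe_bi_effects():
    """The 77 packaged Fisher-z effects for the performance-expectancy →
    behavioral-intention path."""
    return load_pe_bi_effects()


@pytest.fixture(scope="session")
def path_counts():
    """The 67 path-level significant/total counts."""
    return load_path_counts()


@pytest.fixture(scope="session")
def counts_corpus():
    """A record corpus reconstructed from the path-level counts (weight
    analysis depends only on the labels, which this reconstruction
    preserves exactly)."""
    return records_from_counts()
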