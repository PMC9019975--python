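import pytest

from metapile.synthetic import generate_states


@pytest.fixture(scope="session")
def two_state_matrix():
    """600 cells from two moderately separated states; session-cached."""
    return generate_states(n_states=2, n_genes=500, n_cells=600, seed=1,
                           separation=4.0)


@pytest.fixture(scope="session")
def four_state_matrix():
    """1200 cells from four states, for partition recovery tests."""
    return generate_states(n_states=4, n_genes=800, n_cells=1200, seed=2,
                           separation=4.0)
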