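import numpy as np
import pytest

from enzymatch.fixtures import generate_fixture, toy_triad_motif


@pytest.fixture(scope="session")
def toy_motif():
    return toy_triad_motif()


@pytest.fixture(scope="session")
def planted():
    """One representative planted fixture shared across test modules."""
    return generate_fixture(seed=3)


@pytest.fixture(scope="session")
def planted_pool():
    """A small pool of planted fixtures for statistics-flavoured unit tests."""
    return [generate_fixture(seed=s) for s in range(4)]


@pytest.fixture(scope="session")
def matched_pool(planted_pool):
    """Planted fixtures with their (expensive) full matching results, shared
    by every test that inspects emitted matches."""
    from enzymatch.engine import MatchConfig, match_scaffold

    out = []
    for fx in planted_pool:
        matches = match_scaffold(
            fx.scaffold, fx.motif, MatchConfig(seed=0),
            reference_residues=fx.catalytic_site_ids,
        )
        out.append((fx, matches))
    return out


def truth_labels(fixture):
    return {k: f"{v[0]}{v[1]}{v[2]}" for k, v in fixture.truth.assignment.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160531)
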