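"""Shared fixtures: the synthetic monomer pools and arrays used across tests.

Everything is generated programmatically with fixed seeds; the
session scope keeps the edit-distance-heavy arrays computed once.
"""

import pytest

import grmhor as g
from grmhor.synth_fixtures import gen_consensus_family


@pytest.fixture(scope="session")
def pool12():
    """12 mutually >20%-divergent 171-bp monomers: 10 base types + 2 novel."""
    return g.gen_divergent_monomers(g.FixtureSpec(n_types=12, seed=1))


@pytest.fixture(scope="session")
def base10(pool12):
    return pool12[:10]


@pytest.fixture(scope="session")
def novel_pair(pool12):
    return tuple(pool12[10:])


@pytest.fixture(scope="session")
def canonical100(base10):
    """10 types repeated 10x in fixed order: the pure Willard's array."""
    return g.build_canonical_array(base10, 10)


@pytest.fixture(scope="session")
def canonical_vector(canonical100):
    return g.build_next_similar(canonical100)


@pytest.fixture(scope="session")
def case2_array(canonical100, novel_pair):
    """Canonical array after the fixed deletions and novel-pair insertions."""
    return g.apply_case2_edits(canonical100, novel_pair)


@pytest.fixture(scope="session")
def case2_vector(case2_array):
    return g.build_next_similar(case2_array)


@pytest.fixture(scope="session")
def cascading110(base10):
    """10 copies of the 11-monomer unit t1..t6, t2, t7..t10."""
    return g.build_cascading_array(base10, 10)


@pytest.fixture(scope="session")
def consensus_family():
    """(consensus, 10 types within 16.5% of it, mutually >12% divergent)."""
    return gen_consensus_family(seed=5)
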