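import numpy as np
import pytest

from clonering import (
    HaploidGenotype,
    Locus,
    MultiGenetConfig,
    Panel,
    RingSimConfig,
    SampleRecord,
    simulate_fairy_ring,
    simulate_multigenet_site,
)


@pytest.fixture(scope="session")
def toy_panel():
    return Panel(
        (
            Locus("aest07", "SSR", frozenset({150, 152, 154})),
            Locus("aest18", "SSR", frozenset({201, 203})),
            Locus("aest15", "SSR", frozenset({118})),
        )
    )


def make_record(sample_id, alleles, mat, *, site="S", year=2019, role="gleba",
                x=None, y=None):
    return SampleRecord(
        sample_id, site, year, role, x, y, HaploidGenotype(tuple(alleles), mat)
    )


@pytest.fixture(scope="session")
def ring_sim():
    """Default fairy-ring simulation: 205 gleba records, 2 maternal genets."""
    return simulate_fairy_ring(RingSimConfig(seed=11))


@pytest.fixture(scope="session")
def site_sim():
    """Default multi-genet site with IBD, patchy MATs and local mating."""
    return simulate_multigenet_site(MultiGenetConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
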