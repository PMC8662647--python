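import pytest

import enac_decay as ed


@pytest.fixture(scope="session")
def intact_locus():
    """One unmutated synthetic locus shared by read-only tests."""
    return ed.generate_locus_set(ed.LocusSpec(seed=11))


@pytest.fixture(scope="session")
def intact_hits(intact_locus):
    return ed.map_exons(intact_locus.locus, intact_locus.reference)
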