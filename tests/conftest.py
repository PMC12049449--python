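import pytest

from nickscope import CircularSequence, build_index, make_plasmid


@pytest.fixture(scope="session")
def tiny_ref() -> CircularSequence:
    """The 10-bp worked-example circle used throughout the docs."""
    return CircularSequence("tiny", "ACGTACGTAA")


@pytest.fixture(scope="session")
def plasmid() -> CircularSequence:
    """A realistic-scale synthetic plasmid (5.5 kb)."""
    return make_plasmid(5500, seed=11)


@pytest.fixture(scope="session")
def plasmid_index(plasmid):
    return build_index(plasmid)
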