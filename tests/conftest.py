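import pytest

from rnaet.seqio import Alignment
from rnaet.structmetrics import contact_graph_3d
from rnaet.synthfix import FixtureSpec, make_fixture


@pytest.fixture
def aln4():
    """Four sequences whose UPGMA tree is ((s1,s2),(s3,s4)); column 1 = A,A,G,G."""
    return Alignment(["s1", "s2", "s3", "s4"], ["AAAA", "AAAC", "GGGA", "GGGC"])


@pytest.fixture(scope="session")
def default_bundle():
    return make_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def default_graph(default_bundle):
    return contact_graph_3d(default_bundle.structure)
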