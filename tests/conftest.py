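import pytest

from ampliclone.align import Scoring
from ampliclone.references import ReferencePair, default_reference_pair


@pytest.fixture(scope="session")
def refs() -> ReferencePair:
    """The packaged 400-nt synthetic amplicon with a 12-nt replacement."""
    return default_reference_pair()


@pytest.fixture(scope="session")
def scoring() -> Scoring:
    return Scoring()


@pytest.fixture(scope="session")
def small_refs() -> ReferencePair:
    """A tiny hand-written reference pair for worked examples.

    WT:  60 nt, cut site 30, a 6-nt block replaced in the HDR sequence,
    edit window [24, 42).
    """
    wt = "ATCGGCTAAGCTGGATCCAGTACCTGGCAATGCTAGCCGGTTACGGATCAGGCTTAAGCC"
    hdr = wt[:30] + "TTTAAA" + wt[36:]
    assert len(wt) == 60
    return ReferencePair(
        name="mini",
        wt_seq=wt,
        hdr_seq=hdr,
        cut_site=30,
        edit_window=(24, 42),
    )
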