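import pytest

from peptidogenomics.chem import Peptide
from peptidogenomics.validation import CandidateSequence

HEPCIDIN = "DTHFPICIFCCGCCKTPKCGFCCRT"
RECOMBINANT = "DTHFPICIFCCGCCKTPKCGLCCKT"


@pytest.fixture
def hepcidin():
    return Peptide(HEPCIDIN, n_disulfides=4)


@pytest.fixture
def recombinant():
    return Peptide(RECOMBINANT, n_disulfides=4)


@pytest.fixture
def table1_candidates():
    """The reported canine hepcidin-25 translations (accession table rows)."""
    return [
        CandidateSequence("AAT95397.1", "DTHFPICIFCCGCCKTPKCGLCCIT", "mRNA"),
        CandidateSequence("AAW82336.1", "DTHFPICIFCCGCCKTPKCGFCCKT", "mRNA"),
        CandidateSequence("AAV40979.1", "DTHFPICIFCCGCCKTPKCGLCCKT", "mRNA"),
        CandidateSequence("recombinant", RECOMBINANT, "recombinant"),
        CandidateSequence("this-study", HEPCIDIN, "peptide"),
    ]
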