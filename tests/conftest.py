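import numpy as np
import pytest

from firtool.peptides import ModifiedPeptide, parse_modified_sequence

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng: np.random.Generator, max_len: int = 300, min_len: int = 5,
                   p_phospho: float = 0.2) -> ModifiedPeptide:
    """Seeded random peptide with random phospho marks on S/T/Y."""
    n = int(rng.integers(min_len, max_len + 1))
    residues = "".join(rng.choice(list(AA20), size=n))
    marks = {
        i + 1
        for i, aa in enumerate(residues)
        if aa in "STY" and rng.random() < p_phospho
    }
    return ModifiedPeptide(residues, frozenset(marks))


@pytest.fixture
def ccpg1_fir2_15mer():
    """CCPG1 residues 99-113 around the FIR2 core (unmodified)."""
    return parse_modified_sequence("TASDDSDIVTLEPPK", numbering_offset=99)


@pytest.fixture
def ccpg1_fir2_13mer():
    """The 13-residue synthetic phospho-CCPG1 FIR2 peptide (residues 101-113)."""
    return parse_modified_sequence("SDDpSDIVTLEPPK", numbering_offset=101)


@pytest.fixture
def p_optn_lir():
    """The 13-residue phospho-Optineurin LIR peptide (residues 173-185)."""
    return parse_modified_sequence("SSEDpSFVEIRMAE", numbering_offset=173)


@pytest.fixture
def optn_ms_peptide():
    """The tryptic Optineurin phosphopeptide observed by HCD MS/MS."""
    return parse_modified_sequence("LNSSGSSEDsFVEIR")
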