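import pytest

from xldna.chem import Oligo
from xldna.conjugates import CrossLinkChemistry
from xldna.io import parse_oligo_spec
from xldna.remnants import Remnant

# The worked example throughout the suite: the tryptic peptide of a DNA
# 3'-end-processing enzyme that photo-cross-links via its F residue (site 5
# within the peptide; F259 in full-length numbering, offset +250 from the
# peptide start) to a 5-iodo-dU placed at the -2 or -3 position of a 20-mer.
PEPTIDE = "LDIAFGTHATK"
SITE = 5  # the F residue
OLIGO_MINUS2 = "GTAGAGGATCTAAAAGAC(5IdU)T-Biotin-TEG"
OLIGO_MINUS3 = "GTAGAGGATCTAAAAGA(5IdU)TT-Biotin-TEG"
OLIGO_CONTROL = "GTAGAGGATCTAAAAGACTT-Biotin-TEG"

# A small synthetic parent protein containing the worked peptide flanked by
# tryptic context (synthetic — not any real protein sequence).
PROTEIN = "MKTAYIAKQRLDIAFGTHATKGVNDNEEGFFSAR"


@pytest.fixture(scope="session")
def chemistry() -> CrossLinkChemistry:
    return CrossLinkChemistry()


@pytest.fixture(scope="session")
def oligo_minus2() -> Oligo:
    return parse_oligo_spec(OLIGO_MINUS2)


@pytest.fixture(scope="session")
def oligo_minus3() -> Oligo:
    return parse_oligo_spec(OLIGO_MINUS3)


@pytest.fixture(scope="session")
def oligo_control() -> Oligo:
    return parse_oligo_spec(OLIGO_CONTROL)


@pytest.fixture(scope="session")
def remnant_mono() -> Remnant:
    """The P1 limit product: the cross-linked 5'-nucleotide-monophosphate."""
    return Remnant(codes=("5IdU",), reactive_index=1)


@pytest.fixture(scope="session")
def remnant_dimer() -> Remnant:
    """Incomplete P1 digestion: reactive nucleotide plus the 3'-adjacent dT."""
    return Remnant(codes=("5IdU", "dT"), reactive_index=1)
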