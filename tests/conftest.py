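import numpy as np
import pytest

from plastidkit.synthetic_data import _random_seq

MINI_GENBANK = """\
LOCUS       TESTREC                   60 bp    DNA     circular PLN 01-JAN-2020
DEFINITION  minimal synthetic test record.
ACCESSION   TESTREC
VERSION     TESTREC.1
FEATURES             Location/Qualifiers
     source          1..60
     gene            10..18
                     /gene="tufA"
     CDS             10..18
                     /gene="tufA"
     CDS             complement(join(20..28,35..40))
                     /gene="xyzB"
     gene            45..50
                     /gene="psbZ"
                     /pseudo
ORIGIN
        1 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
//
"""


@pytest.fixture
def mini_genbank(tmp_path):
    path = tmp_path / "mini.gb"
    path.write_text(MINI_GENBANK)
    return path


@pytest.fixture
def random_seq():
    def make(length: int, seed: int = 0, gc: float = 0.5) -> str:
        return _random_seq(np.random.default_rng(seed), length, gc)
    return make


def substitute(seq: str, pos: int) -> str:
    """Deterministic single-base substitution (transversion-style swap)."""
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    return seq[:pos] + swap[seq[pos]] + seq[pos + 1:]
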