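import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

WT_PEPTIDE = "SLLMWITQV"

NY1_PATTERN = (
    "[ACFGHILMNQRSTVWY]-[ACILMQV]-[ACDFGHILMNPQSTVW]-[FILMT]-W-[FILMV]-"
    "[CFILMQRSTVY]-[QT]-[ACITV]"
)
NY2_PATTERN = (
    "[ACFHIMNPQRSTVWY]-[FILMVW]-[ILMQV]-[IM]-W-[FILMPVW]-[ACFGILMNQRSTV]-"
    "[ACDEFGHKLMNPQRSTVWY]-[ACFGILSTV]"
)


@pytest.fixture
def ny1_motif():
    from xscan.motif import parse_motif

    return parse_motif(NY1_PATTERN, motif_id="NY_1")


@pytest.fixture
def ny2_motif():
    from xscan.motif import parse_motif

    return parse_motif(NY2_PATTERN, motif_id="NY_2")


@pytest.fixture
def ny1_profile(ny1_motif):
    from xscan.activation import ToleranceProfile

    return ToleranceProfile(wild_type=WT_PEPTIDE, allowed=ny1_motif.classes)


@pytest.fixture
def ny2_profile(ny2_motif):
    from xscan.activation import ToleranceProfile

    return ToleranceProfile(wild_type=WT_PEPTIDE, allowed=ny2_motif.classes)


def random_matrix(rng, wild_type=WT_PEPTIDE, normalized=False):
    """A random activation matrix over all 20 residues (testing helper)."""
    import pandas as pd

    from xscan.activation import AMINO_ACIDS, ActivationMatrix

    L = len(wild_type)
    data = rng.uniform(0.0, 120.0, size=(L, 20))
    values = pd.DataFrame(data, index=range(1, L + 1), columns=list(AMINO_ACIDS))
    if normalized:
        for i, wt in enumerate(wild_type, start=1):
            values.loc[i] = values.loc[i] / values.at[i, wt] * 100.0
    return ActivationMatrix(
        wild_type=wild_type, values=values, normalized=normalized
    )


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      -1.200   0.500   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       0.000  -0.400   1.200  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1      -1.200   0.500   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       0.000   0.000   0.000  0.30  0.00           C
ATOM      3  CA BSER A   1       0.100   0.000   0.000  0.70  0.00           C
ATOM      4  OG  SER A   1       0.500   1.000   1.000  1.00  0.00           O
HETATM    5  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
END
"""
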