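import pytest

from dynasel.popgen_io import PopulationAlignment


@pytest.fixture
def two_codon_alignment() -> PopulationAlignment:
    """Three identical ingroup haplotypes plus sister, two codons of ATG AAA."""
    return PopulationAlignment(
        name="toy",
        ingroup=("ATGAAA", "ATGAAA", "ATGAAA"),
        sister="ATGAAA",
    )


def make_alignment(ingroup, sister, outgroup=None, name="gene"):
    return PopulationAlignment(
        name=name, ingroup=tuple(ingroup), sister=sister, outgroup=outgroup
    )


@pytest.fixture
def make_aln():
    return make_alignment
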