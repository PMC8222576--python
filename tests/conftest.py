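import numpy as np
import pytest

from ecesim import CodonTable, QuaternaryGenome


@pytest.fixture(scope="session")
def table() -> CodonTable:
    return CodonTable.default()


def make_genome(codons: list[str]) -> QuaternaryGenome:
    """Build a genome from a list of codon strings."""
    return QuaternaryGenome.from_string("".join(codons))


def gene_genome(span: list[str], pad: int = 0) -> QuaternaryGenome:
    """A genome with one gene holding `span`, padded with unexpressed
    feature codons (002) outside the gene."""
    filler = ["002"] * pad
    return make_genome(filler + ["111"] + span + ["333"] + filler)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
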