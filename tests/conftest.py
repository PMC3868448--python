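"""Shared fixtures: standard haplotypes/units and a synthetic diagnostic-rule set."""

from __future__ import annotations

import pytest

from navdup.locus_model import (
    DEFAULT_DUPLICATION,
    MUT1011,
    MUT1016,
    WILD_A,
    WILD_B,
    ChromosomeUnit,
    Genotype,
)

# Synthetic clone sequences: positions 10-13 carry the 1011 codon, the intron
# class and 1016 state are marked by unique motifs.  The rules ship with the
# fixture, mirroring how an assay-specific config would be supplied.
SEQ_RULES = {
    "site1011": {"kind": "position", "start": 10, "end": 13, "calls": {"ATT": "Ile", "ATG": "Met"}},
    "intron": {"kind": "motif", "calls": {"A": "CCGGTACGT", "B": "CCGGCATGA"}},
    "site1016": {"kind": "motif", "calls": {"Val": "TTGTACC", "Ile": "TTATACC"}},
}

_CODON_1011 = {"Ile": "ATT", "Met": "ATG"}
_INTRON_MOTIF = {"A": "CCGGTACGT", "B": "CCGGCATGA"}
_MOTIF_1016 = {"Val": "TTGTACC", "Ile": "TTATACC"}


def build_clone_sequence(haplotype) -> str:
    """A sequence that SEQ_RULES calls back to ``haplotype``."""
    return (
        "GCGCGCGCGC"
        + _CODON_1011[haplotype.site1011]
        + "AAAA"
        + _INTRON_MOTIF[haplotype.intron]
        + "AAAA"
        + _MOTIF_1016[haplotype.site1016]
        + "AAAA"
    )


@pytest.fixture
def seq_rules():
    return SEQ_RULES


@pytest.fixture
def wild_unit():
    return ChromosomeUnit.single(WILD_B)


@pytest.fixture
def mut1011_unit():
    return ChromosomeUnit.single(MUT1011)


@pytest.fixture
def dup_unit():
    return DEFAULT_DUPLICATION


@pytest.fixture
def wild_homozygote(wild_unit):
    return Genotype.of(wild_unit, wild_unit)


@pytest.fixture
def dup_heterozygote(wild_unit, dup_unit):
    return Genotype.of(wild_unit, dup_unit)


@pytest.fixture
def dup_homozygote(dup_unit):
    return Genotype.of(dup_unit, dup_unit)
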