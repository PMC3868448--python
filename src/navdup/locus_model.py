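"""Genetic data model for a two-site sodium-channel locus with optional tandem duplication.

A haplotype combines the amino-acid state at codon 1011 (Ile/Met), the
intron-20 sequence class (A/B) and the state at codon 1016 (Val/Ile) carried
on one gene copy.  A transmissible chromosome unit is either a lone haplotype
or a tandem pair of haplotypes inherited as a single linkage block
("duplicated unit").  Allele-specific PCR and intron-size PCR report only the
presence or absence of each variant, never its dosage, so a duplicated unit
carrying both a wild-type and a mutant haplotype produces the same molecular
phenotype as a conventional heterozygote.  :func:`phenotype_of` implements
that masking operator; :func:`gametes_of` gives the Mendelian transmission of
units (a duplicated unit segregates intact).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations_with_replacement
from typing import Dict, Iterable, List, Sequence, Tuple

ALLELES_1011: Tuple[str, ...] = ("Ile", "Met")
INTRON_TYPES: Tuple[str, ...] = ("A", "B")
ALLELES_1016: Tuple[str, ...] = ("Val", "Ile")

CALLS_1011: Tuple[str, ...] = ("Ile/Ile", "Ile/Met", "Met/Met")
CALLS_INTRON: Tuple[str, ...] = ("AA", "AB", "BB")
CALLS_1016: Tuple[str, ...] = ("Val/Val", "Val/Ile", "Ile/Ile")

_HAPLOTYPE_RE = re.compile(r"1011(ile|met)\+([ab])\+1016(val|ile)")


@dataclass(frozen=True)
class Haplotype:
    """Joint state (1011 allele, intron type, 1016 allele) of one gene copy."""

    site1011: str
    intron: str
    site1016: str

    def __post_init__(self) -> None:
        if self.site1011 not in ALLELES_1011:
            raise ValueError(f"site1011 must be one of {ALLELES_1011}: {self.site1011!r}")
        if self.intron not in INTRON_TYPES:
            raise ValueError(f"intron must be one of {INTRON_TYPES}: {self.intron!r}")
        if self.site1016 not in ALLELES_1016:
            raise ValueError(f"site1016 must be one of {ALLELES_1016}: {self.site1016!r}")

    @property
    def rank(self) -> Tuple[int, int, int]:
        """Canonical sort key: wild-type states first."""
        return (
            ALLELES_1011.index(self.site1011),
            INTRON_TYPES.index(self.intron),
            ALLELES_1016.index(self.site1016),
        )

    @property
    def is_observed_class(self) -> bool:
        """True for the four haplotype classes seen in field surveys."""
        return self in OBSERVED_HAPLOTYPES

    @property
    def is_model_excluded(self) -> bool:
        """True for the double-mutant recombinant, excluded from the model."""
        return self.site1011 == "Met" and self.site1016 == "Ile"

    @property
    def warning(self) -> bool:
        """Soft flag for haplotypes outside the observed class (never an error)."""
        return not self.is_observed_class

    def __str__(self) -> str:
        return f"1011{self.site1011}+{self.intron}+1016{self.site1016}"

    @classmethod
    def parse(cls, text: str) -> "Haplotype":
        """Parse the ``"1011Ile+B+1016Val"`` syntax, case-insensitively."""
        m = _HAPLOTYPE_RE.fullmatch(text.strip().lower())
        if m is None:
            raise ValueError(f"cannot parse haplotype string: {text!r}")
        return cls(m.group(1).capitalize(), m.group(2).upper(), m.group(3).capitalize())


#: Wild-type at both sites, intron class B (the reference-strain haplotype).
WILD_B = Haplotype("Ile", "B", "Val")
#: Wild-type at both sites, intron class A.
WILD_A = Haplotype("Ile", "A", "Val")
#: 1011Met mutant (always intron A in the observed class).
MUT1011 = Haplotype("Met", "A", "Val")
#: 1016Ile mutant (always intron A in the observed class).
MUT1016 = Haplotype("Ile", "A", "Ile")

OBSERVED_HAPLOTYPES = frozenset({WILD_B, WILD_A, MUT1011, MUT1016})

ALL_HAPLOTYPES: Tuple[Haplotype, ...] = tuple(
    sorted(
        (
            Haplotype(a, i, b)
            for a in ALLELES_1011
            for i in INTRON_TYPES
            for b in ALLELES_1016
        ),
        key=lambda h: h.rank,
    )
)


@dataclass(frozen=True, eq=False)
class ChromosomeUnit:
    """A transmissible unit: one haplotype, or a tandem pair inherited as a block.

    The order of the pair in a duplicated unit is stored but carries no
    meaning (which copy is upstream is unknown); equality and hashing ignore
    it.
    """

    haplotypes: Tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "haplotypes", tuple(self.haplotypes))
        if len(self.haplotypes) not in (1, 2):
            raise ValueError("a chromosome unit carries 1 (single) or 2 (duplicated) haplotypes")

    @property
    def kind(self) -> str:
        return "single" if len(self.haplotypes) == 1 else "duplicated"

    @property
    def is_duplicated(self) -> bool:
        return len(self.haplotypes) == 2

    @property
    def _key(self) -> tuple:
        return (len(self.haplotypes), tuple(sorted(h.rank for h in self.haplotypes)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChromosomeUnit):
            return NotImplemented
        return self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __str__(self) -> str:
        return " & ".join(str(h) for h in self.haplotypes)

    @classmethod
    def single(cls, hap: Haplotype) -> "ChromosomeUnit":
        return cls((hap,))

    @classmethod
    def duplicated(cls, first: Haplotype, second: Haplotype) -> "ChromosomeUnit":
        return cls((first, second))


#: Default duplicated unit: wild-type-B linked in tandem with the 1011Met haplotype.
DEFAULT_DUPLICATION = ChromosomeUnit.duplicated(WILD_B, MUT1011)


@dataclass(frozen=True, eq=False)
class Genotype:
    """Unordered pair of chromosome units (one inherited from each parent)."""

    units: Tuple[ChromosomeUnit, ChromosomeUnit]

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        if len(self.units) != 2:
            raise ValueError("a genotype is a pair of chromosome units")

    @property
    def _key(self) -> tuple:
        return tuple(sorted(u._key for u in self.units))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __str__(self) -> str:
        return " / ".join(str(u) for u in self.units)

    def all_haplotypes(self) -> List[Haplotype]:
        """Every haplotype physically present (a duplicated unit contributes two)."""
        return [h for u in self.units for h in u.haplotypes]

    @classmethod
    def of(cls, unit1: ChromosomeUnit, unit2: ChromosomeUnit) -> "Genotype":
        return cls((unit1, unit2))


@dataclass(frozen=True)
class MolecularPhenotype:
    """What the PCR assays report: per-feature presence of each variant.

    Each call is the unordered set of states present anywhere in the genotype
    — dosage is discarded, which is exactly why duplication carriers mimic
    heterozygotes.
    """

    call1011: str
    intron_call: str
    call1016: str

    def __post_init__(self) -> None:
        if self.call1011 not in CALLS_1011:
            raise ValueError(f"bad 1011 call: {self.call1011!r}")
        if self.intron_call not in CALLS_INTRON:
            raise ValueError(f"bad intron call: {self.intron_call!r}")
        if self.call1016 not in CALLS_1016:
            raise ValueError(f"bad 1016 call: {self.call1016!r}")

    @property
    def site_calls(self) -> Tuple[str, str]:
        """(1011 call, 1016 call) — the category key used by phenotype tables."""
        return (self.call1011, self.call1016)

    def __str__(self) -> str:
        return f"{self.call1011} + {self.intron_call} + {self.call1016}"

    @classmethod
    def parse(cls, text: str) -> "MolecularPhenotype":
        parts = [p.strip() for p in text.split("+")]
        if len(parts) != 3:
            raise ValueError(f"cannot parse molecular phenotype: {text!r}")
        return cls(parts[0], parts[1], parts[2])


def _pair_call(states: Iterable[str], order: Sequence[str], sep: str = "/") -> str:
    state_set = set(states)
    present = [s for s in order if s in state_set]
    if not present:
        raise ValueError("no state present")
    if len(present) == 1:
        present = present * 2
    return sep.join(present)


def phenotype_of_haplotypes(haplotypes: Sequence[Haplotype]) -> MolecularPhenotype:
    """Presence/absence calls over an arbitrary collection of haplotypes."""
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    return MolecularPhenotype(
        call1011=_pair_call((h.site1011 for h in haplotypes), ALLELES_1011),
        intron_call=_pair_call((h.intron for h in haplotypes), INTRON_TYPES, sep=""),
        call1016=_pair_call((h.site1016 for h in haplotypes), ALLELES_1016),
    )


def phenotype_of(genotype: Genotype) -> MolecularPhenotype:
    """AS-PCR masking operator: genotype -> observable molecular phenotype."""
    return phenotype_of_haplotypes(genotype.all_haplotypes())


def gametes_of(genotype: Genotype) -> Dict[ChromosomeUnit, Fraction]:
    """Gamete distribution: each unit with probability 1/2, transmitted intact."""
    u1, u2 = genotype.units
    if u1 == u2:
        return {u1: Fraction(1)}
    return {u1: Fraction(1, 2), u2: Fraction(1, 2)}


def category_key(phenotype: MolecularPhenotype) -> Tuple[str, str]:
    """Phenotype-table category of a phenotype (intron reported separately)."""
    return phenotype.site_calls


def category_rank(key: Tuple[str, str]) -> Tuple[int, int]:
    return (CALLS_1011.index(key[0]), CALLS_1016.index(key[1]))


def category_column(key: Tuple[str, str]) -> str:
    """CSV column stem for a category, e.g. ``("Ile/Met", "Val/Val")`` -> ``IleMet_ValVal``."""
    return key[0].replace("/", "") + "_" + key[1].replace("/", "")


def enumerate_phenotype_categories(
    haplotypes: Iterable[Haplotype],
) -> List[MolecularPhenotype]:
    """All distinct phenotype categories reachable from pairs of single units.

    Categories are de-duplicated on their (1011, 1016) site calls and returned
    in the canonical table order (1011 call major, 1016 call minor).
    """
    haps = sorted(set(haplotypes), key=lambda h: h.rank)
    if not 1 <= len(haps) <= 4:
        raise ValueError("haplotype set must contain between 1 and 4 haplotypes")
    seen = set()
    categories: List[MolecularPhenotype] = []
    for hi, hj in combinations_with_replacement(haps, 2):
        ph = phenotype_of_haplotypes([hi, hj])
        if ph.site_calls not in seen:
            seen.add(ph.site_calls)
            categories.append(ph)
    categories.sort(key=lambda ph: category_rank(ph.site_calls))
    return categories
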