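"""Per-specimen haplotype profiling from sequenced clones of amplified gene copies.

Each specimen contributes several cloned amplicon sequences; each clone is
called to a haplotype either directly (tabulated calls) or through a
user-supplied diagnostic-rule configuration (:func:`classify_sequence`).
A specimen showing three or more distinct haplotypes cannot be explained by
two single-copy chromosomes and is flagged as duplication evidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO

from .locus_model import (
    Haplotype,
    MolecularPhenotype,
    phenotype_of_haplotypes,
)

FEATURES = ("site1011", "intron", "site1016")


class UncallableSequenceError(ValueError):
    """A clone sequence cannot be assigned a state for some feature."""


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced clone of one specimen, already called to a haplotype."""

    specimen: str
    clone: str
    call: Haplotype


@dataclass
class SpecimenHaplotypeProfile:
    """Haplotypes supported by the clones of one specimen."""

    specimen: str
    support: Dict[Haplotype, int]
    n_haplotypes: int
    duplication_flag: bool
    inferred_phenotype: MolecularPhenotype

    @property
    def haplotypes(self) -> List[Haplotype]:
        return sorted(self.support, key=lambda h: h.rank)


def collapse_clones(
    records: Sequence[CloneRecord], min_support: int = 1
) -> SpecimenHaplotypeProfile:
    """Collapse the clone calls of one specimen into a haplotype profile.

    Haplotypes backed by fewer than ``min_support`` clones are discarded
    (raise ``min_support`` to absorb PCR/cloning artifacts).  A profile with
    three or more retained haplotypes is flagged as duplication evidence.
    """
    if not records:
        raise ValueError("empty record set")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    specimens = {r.specimen for r in records}
    if len(specimens) != 1:
        raise ValueError(f"records span multiple specimens: {sorted(specimens)}")
    seen = {(r.specimen, r.clone) for r in records}
    if len(seen) != len(records):
        raise ValueError("duplicate (specimen, clone) identifiers")
    counts = Counter(r.call for r in records)
    support = {h: c for h, c in counts.items() if c >= min_support}
    if not support:
        raise ValueError(
            f"no haplotype reaches min_support={min_support} "
            f"(max observed support {max(counts.values())})"
        )
    haps = sorted(support, key=lambda h: h.rank)
    return SpecimenHaplotypeProfile(
        specimen=records[0].specimen,
        support=dict(sorted(support.items(), key=lambda kv: kv[0].rank)),
        n_haplotypes=len(haps),
        duplication_flag=len(haps) >= 3,
        inferred_phenotype=phenotype_of_haplotypes(haps),
    )


def collapse_all(
    records: Iterable[CloneRecord], min_support: int = 1
) -> List[SpecimenHaplotypeProfile]:
    """Group records by specimen and collapse each group (input order kept)."""
    grouped: Dict[str, List[CloneRecord]] = {}
    for r in records:
        grouped.setdefault(r.specimen, []).append(r)
    return [collapse_clones(rs, min_support=min_support) for rs in grouped.values()]


@dataclass
class HaplotypeTally:
    """Cross-specimen summary of a profiled sample set."""

    specimen_counts: Dict[Haplotype, int]
    n_distinct: int
    n_flagged: int
    n_specimens: int


def tally_haplotypes(profiles: Sequence[SpecimenHaplotypeProfile]) -> HaplotypeTally:
    """Count, per haplotype, the specimens supporting it; count flagged specimens."""
    if not profiles:
        raise ValueError("no profiles to tally")
    counts: Counter = Counter()
    for p in profiles:
        counts.update(set(p.support))
    ordered = dict(sorted(counts.items(), key=lambda kv: kv[0].rank))
    return HaplotypeTally(
        specimen_counts=ordered,
        n_distinct=len(ordered),
        n_flagged=sum(1 for p in profiles if p.duplication_flag),
        n_specimens=len(profiles),
    )


# ---------------------------------------------------------------------------
# Rule-driven sequence classification
# ---------------------------------------------------------------------------
#
# The diagnostic nucleotides for the codon changes and the A/B intron classes
# are assay-specific, so they are supplied as configuration rather than baked
# in.  A rule config maps each feature to one predicate:
#
#   site1011: {kind: motif,    calls: {Ile: "ATTGGC", Met: "ATGGGC"}}
#   intron:   {kind: length,   threshold: 250, at_least: "B", below: "A"}
#   site1016: {kind: position, start: 88, end: 91, calls: {GTA: "Val", ATA: "Ile"}}
#
# "motif":    exactly one of the listed motifs must occur (exactly once).
# "length":   sequence (or start/end window) length against a threshold.
# "position": the exact window seq[start:end] must be a listed key.


def _apply_motif_rule(seq: str, feature: str, rule: Mapping) -> str:
    hits = []
    for state, motif in rule["calls"].items():
        count = seq.count(motif.upper())
        if count > 1:
            raise UncallableSequenceError(
                f"{feature}: motif {motif!r} occurs {count} times (ambiguous)"
            )
        if count == 1:
            hits.append(state)
    if not hits:
        raise UncallableSequenceError(f"{feature}: no diagnostic motif found")
    if len(hits) > 1:
        raise UncallableSequenceError(f"{feature}: multiple motifs matched {hits}")
    return hits[0]


def _apply_length_rule(seq: str, feature: str, rule: Mapping) -> str:
    start = rule.get("start", 0)
    end = rule.get("end", len(seq))
    if end > len(seq):
        raise UncallableSequenceError(f"{feature}: sequence shorter than rule window")
    window = seq[start:end]
    return rule["at_least"] if len(window) >= rule["threshold"] else rule["below"]


def _apply_position_rule(seq: str, feature: str, rule: Mapping) -> str:
    start, end = rule["start"], rule["end"]
    if end > len(seq):
        raise UncallableSequenceError(f"{feature}: sequence shorter than rule window")
    window = seq[start:end]
    calls = {k.upper(): v for k, v in rule["calls"].items()}
    if window not in calls:
        raise UncallableSequenceError(f"{feature}: window {window!r} matches no rule")
    return calls[window]


_RULE_KINDS = {
    "motif": _apply_motif_rule,
    "length": _apply_length_rule,
    "position": _apply_position_rule,
}


def classify_sequence(sequence: str, rules: Mapping) -> Haplotype:
    """Call a haplotype from a clone sequence using a diagnostic-rule config."""
    seq = str(sequence).upper()
    missing = [f for f in FEATURES if f not in rules]
    if missing:
        raise ValueError(f"rules missing features: {missing}")
    states = {}
    for feature in FEATURES:
        rule = rules[feature]
        kind = rule.get("kind")
        if kind not in _RULE_KINDS:
            raise ValueError(f"{feature}: unknown rule kind {kind!r}")
        states[feature] = _RULE_KINDS[kind](seq, feature, rule)
    return Haplotype(states["site1011"], states["intron"], states["site1016"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_clone_csv(path) -> List[CloneRecord]:
    """Read clone calls: ``specimen,clone,site1011,intron,site1016``."""
    df = pd.read_csv(path)
    required = ["specimen", "clone", "site1011", "intron", "site1016"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    return [
        CloneRecord(
            specimen=str(row.specimen),
            clone=str(row.clone),
            call=Haplotype(
                str(row.site1011).capitalize(),
                str(row.intron).upper(),
                str(row.site1016).capitalize(),
            ),
        )
        for row in df.itertuples()
    ]


def load_rules(path) -> Mapping:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_clone_fasta(path, rules: Mapping) -> List[CloneRecord]:
    """Read clone sequences (record id ``specimen|clone``) and call them via rules."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"FASTA id {rec.id!r} is not 'specimen|clone'")
        specimen, clone = rec.id.split("|", 1)
        records.append(
            CloneRecord(specimen=specimen, clone=clone, call=classify_sequence(str(rec.seq), rules))
        )
    return records


def profiles_frame(profiles: Sequence[SpecimenHaplotypeProfile]) -> pd.DataFrame:
    """X-mark table: one row per specimen, one column per observed haplotype."""
    all_haps = sorted(
        {h for p in profiles for h in p.support}, key=lambda h: h.rank
    )
    rows = []
    for p in profiles:
        row: Dict[str, object] = {"specimen": p.specimen}
        for h in all_haps:
            row[str(h)] = "X" if h in p.support else ""
        row["n_haplotypes"] = p.n_haplotypes
        row["duplication_flag"] = p.duplication_flag
        row["molecular_phenotype"] = str(p.inferred_phenotype)
        rows.append(row)
    return pd.DataFrame(rows)
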