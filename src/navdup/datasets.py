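"""Bundled study datasets.

Small, fully published inputs from a Brazilian *Aedes aegypti* kdr survey:
the per-locality two-site phenotype frequency table, the clone-sequencing
haplotype profiles of 40 specimens, the F1/F2 cross outcomes at site 1011,
and the per-assay mean delta-CT values of the TaqMan copy-number plate.
They serve as packaged fixtures for the CLI and as the acceptance inputs.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from .cross_analysis import CrossObservation
from .clone_typing import CloneRecord
from .hwe_analysis import PopulationPhenotypeSample, sample_from_frequencies
from .locus_model import Haplotype

# locality, status (None = undivided sample), n, observed frequencies of the
# six phenotype categories in canonical order; None marks a category that is
# structurally absent (reduced haplotype model for that locality).
SURVEY_ROWS: Tuple[Tuple[str, Optional[str], int, Tuple[Optional[float], ...]], ...] = (
    ("Aparecida de Goiânia", "R", 18, (0.056, 0.0, 0.222, 0.500, 0.222, 0.0)),
    ("Aparecida de Goiânia", "S", 19, (0.105, 0.053, 0.0, 0.842, 0.0, 0.0)),
    ("Campo Grande", "R", 22, (0.045, 0.273, 0.455, 0.091, 0.136, 0.0)),
    ("Campo Grande", "S", 17, (0.118, 0.118, 0.0, 0.588, 0.176, 0.0)),
    ("Cuiabá", "R", 13, (0.231, 0.0, 0.385, 0.308, 0.077, 0.0)),
    ("Cuiabá", "S", 14, (0.571, 0.143, 0.0, 0.286, 0.0, 0.0)),
    ("Dourados", "R", 16, (0.0, 0.063, 0.500, 0.313, 0.125, 0.0)),
    ("Dourados", "S", 20, (0.250, 0.250, 0.100, 0.350, 0.050, 0.0)),
    ("Fortaleza", "R", 16, (0.250, None, None, 0.750, None, 0.0)),
    ("Fortaleza", "S", 16, (0.313, None, None, 0.688, None, 0.0)),
    ("Maceió", "R", 15, (0.467, None, None, 0.533, None, 0.0)),
    ("Maceió", "S", 15, (0.333, None, None, 0.667, None, 0.0)),
    ("Uberaba", "R", 23, (0.043, 0.087, 0.391, 0.174, 0.304, 0.0)),
    ("Uberaba", "S", 20, (0.300, 0.050, 0.050, 0.400, 0.200, 0.0)),
    ("Boa Vista", None, 20, (0.950, 0.0, 0.050, None, None, None)),
    ("Cachoeiro do Itapemirim", None, 20, (0.200, 0.0, 0.250, 0.200, 0.350, 0.0)),
    ("Colatina", None, 16, (0.0, 0.250, 0.063, 0.625, 0.063, 0.0)),
    ("Foz do Iguaçu", None, 19, (0.0, 0.053, 0.526, 0.053, 0.368, 0.0)),
    ("Ijuí", None, 20, (0.900, None, None, 0.100, None, 0.0)),
    ("Macapá", None, 20, (0.300, None, None, 0.700, None, 0.0)),
    ("Santa Bárbara", None, 16, (0.938, None, None, 0.063, None, 0.0)),
    ("Santa Rosa", None, 20, (0.650, None, None, 0.350, None, 0.0)),
)


def survey_samples() -> List[PopulationPhenotypeSample]:
    """All survey rows as samples (counts recovered by largest remainder)."""
    return [
        sample_from_frequencies(locality, status, n, freqs)
        for locality, status, n, freqs in SURVEY_ROWS
    ]


def survey_sample(locality: str, status: Optional[str] = None) -> PopulationPhenotypeSample:
    """One survey row by locality (and status, for R/S-divided localities)."""
    for row_locality, row_status, n, freqs in SURVEY_ROWS:
        if row_locality.lower() == locality.lower() and (
            status is None or (row_status or "unclassified") == status
        ):
            return sample_from_frequencies(row_locality, row_status, n, freqs)
    raise KeyError(f"no survey sample for {locality!r} / {status!r}")


# Specimen clone-sequencing profiles: specimen id -> haplotype strings observed.
CLONE_PROFILES: Dict[str, Tuple[str, ...]] = {
    # Uberaba
    "UBR-04": ("1011Ile+A+1016Val", "1011Ile+B+1016Val"),
    "UBR-08": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    "UBR-10": ("1011Met+A+1016Val", "1011Ile+A+1016Ile", "1011Ile+B+1016Val"),
    "UBR-S25": ("1011Ile+A+1016Val", "1011Ile+A+1016Ile"),
    "UBR-S26": ("1011Ile+A+1016Val", "1011Ile+A+1016Ile"),
    "UBR-R1": ("1011Ile+A+1016Ile",),
    "UBR-R3": ("1011Ile+A+1016Ile",),
    "UBR-R10": ("1011Ile+B+1016Val",),
    "UBR-R11": ("1011Ile+A+1016Ile", "1011Ile+B+1016Val"),
    "UBR-R13": ("1011Met+A+1016Val", "1011Ile+A+1016Ile", "1011Ile+B+1016Val"),
    "UBR-R20": ("1011Ile+A+1016Ile",),
    "UBR-R22": ("1011Ile+A+1016Ile",),
    "UBR-R26": ("1011Ile+A+1016Ile",),
    # Cuiabá
    "CUI-01": ("1011Ile+A+1016Ile", "1011Ile+B+1016Val"),
    "CUI-02": ("1011Ile+A+1016Val",),
    "CUI-03": ("1011Ile+A+1016Val", "1011Ile+B+1016Val"),
    "CUI-04": ("1011Ile+A+1016Val", "1011Ile+B+1016Val"),
    "CUI-07": ("1011Ile+A+1016Val", "1011Ile+B+1016Val"),
    "CUI-08": ("1011Ile+A+1016Val", "1011Ile+B+1016Val"),
    "CUI-12": ("1011Ile+A+1016Val", "1011Ile+B+1016Val"),
    "CUI-R16": ("1011Ile+A+1016Val", "1011Ile+B+1016Val"),
    "CUI-S15": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    # Aparecida de Goiânia
    "APG-01": ("1011Ile+A+1016Val", "1011Ile+A+1016Ile"),
    "APG-02": ("1011Met+A+1016Val", "1011Ile+A+1016Ile", "1011Ile+B+1016Val"),
    "APG-04": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    "APG-05": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    "APG-06": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    "APG-07": ("1011Met+A+1016Val", "1011Ile+A+1016Ile", "1011Ile+B+1016Val"),
    "APG-08": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    "APG-09": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    "APG-10": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    "APG-11": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    "APG-12": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    # Maceió
    "COM-02": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    "COM-07": ("1011Ile+B+1016Val",),
    "COM-09": ("1011Ile+B+1016Val",),
    # Fortaleza (Henrique Jorge district)
    "hrjg-21": ("1011Met+A+1016Val", "1011Ile+B+1016Val"),
    "hrjg-22": ("1011Ile+A+1016Val",),
    "hrjg-23": ("1011Ile+B+1016Val",),
    "hrjg-28": ("1011Ile+A+1016Val", "1011Ile+B+1016Val"),
}


def clone_survey_records() -> List[CloneRecord]:
    """The published presence-only profiles as one clone record per haplotype."""
    records = []
    for specimen, haps in CLONE_PROFILES.items():
        for i, hap in enumerate(haps, start=1):
            records.append(
                CloneRecord(specimen=specimen, clone=f"c{i}", call=Haplotype.parse(hap))
            )
    return records


# F1 crosses: id, maternal phenotype, paternal phenotype, observed counts.
F1_CROSS_ROWS: Tuple[Tuple[str, str, str, int, int], ...] = (
    ("#1", "Ile/Met", "Ile/Ile", 0, 20),
    ("#2", "Ile/Met", "Ile/Ile", 0, 20),
    ("#3", "Ile/Met", "Ile/Ile", 8, 12),
    ("#4", "Ile/Ile", "Ile/Met", 9, 9),
    ("#5", "Ile/Ile", "Ile/Met", 0, 30),
    ("#6", "Ile/Met", "Ile/Ile", 0, 30),
    ("#7", "Ile/Met", "Ile/Ile", 0, 22),
)

F2_CROSS_ROWS: Tuple[Tuple[str, int, int], ...] = (
    ("#1.1", 5, 25),
    ("#2.1", 7, 23),
)


def f1_crosses() -> List[CrossObservation]:
    return [
        CrossObservation(
            cross_id=cid,
            observed={"Ile/Ile": n_ii, "Ile/Met": n_im, "Met/Met": 0},
            generation="F1",
            parent1_phenotype=p1,
            parent2_phenotype=p2,
        )
        for cid, p1, p2, n_ii, n_im in F1_CROSS_ROWS
    ]


def f2_crosses() -> List[CrossObservation]:
    return [
        CrossObservation(
            cross_id=cid,
            observed={"Ile/Ile": n_ii, "Ile/Met": n_im, "Met/Met": 0},
            generation="F2",
            parent1_phenotype="Ile/Met",
            parent2_phenotype="Ile/Met",
        )
        for cid, n_ii, n_im in F2_CROSS_ROWS
    ]


# Copy-number plate: per-assay mean delta-CT (target minus reference gene)
# for the calibrator strain (Rock), the selected lineage (EE) and their F1.
QPCR_MU_DCT: Dict[str, Tuple[float, ...]] = {
    "Rock": (-0.4, 0.0, -0.7),
    "EE": (-2.7, -2.4, -3.0),
    "Hyb": (-2.0, -1.7, -2.4),
}

QPCR_REFERENCE_LINEAGE = "Rock"


def qpcr_assay_means() -> Dict[str, Tuple[float, ...]]:
    return dict(QPCR_MU_DCT)
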