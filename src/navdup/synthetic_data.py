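"""Seeded generators for every input the analysis pipeline consumes.

Populations are drawn by random union of chromosome units (the null model
the fit test assumes), crosses by independent gamete draws from each parent,
clone reads by uniform sampling of the haplotype slots physically present in
a genotype (with an optional per-clone error), and qPCR plates by Gaussian
CT noise around a copy-number-determined mean.  All generators are fully
determined by their scenario plus an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import datasets
from .clone_typing import CloneRecord
from .copy_number import QpcrMeasurement
from .hwe_analysis import estimate_haplotype_frequencies
from .locus_model import (
    ALLELES_1011,
    ALLELES_1016,
    DEFAULT_DUPLICATION,
    INTRON_TYPES,
    ChromosomeUnit,
    Genotype,
    Haplotype,
    MolecularPhenotype,
    WILD_B,
    category_column,
    enumerate_phenotype_categories,
    gametes_of,
    phenotype_of,
)


@dataclass
class PopulationScenario:
    """Random-union diploid population over declared chromosome units."""

    unit_freqs: Dict[ChromosomeUnit, float]
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.unit_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"unit frequencies sum to {total}, expected 1")
        if any(f < 0 for f in self.unit_freqs.values()):
            raise ValueError("unit frequencies must be non-negative")
        if self.n <= 0:
            raise ValueError("n must be positive")


@dataclass
class QpcrScenario:
    """Copy-number plate design: lineages with true copy counts plus CT noise."""

    copies: Dict[str, float]
    reference_lineage: str
    noise_sd: float = 0.0
    ct_baseline: float = 22.0
    dct_offset: float = 0.0
    n_assays: int = 3
    n_pools: int = 1
    n_replicates: int = 3
    copy_jitter_sd: float = 0.0  # per-pool jitter on log2(copies); default off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_lineage not in self.copies:
            raise ValueError("reference lineage must appear in the copies map")
        if any(c < 1 for c in self.copies.values()):
            raise ValueError("copy counts must be >= 1")
        if self.noise_sd < 0 or self.copy_jitter_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def simulate_population(
    scenario: PopulationScenario,
) -> List[Tuple[Genotype, MolecularPhenotype]]:
    """Each individual is the union of two units drawn independently by frequency."""
    rng = np.random.default_rng(scenario.seed)
    units = list(scenario.unit_freqs)
    probs = np.array([scenario.unit_freqs[u] for u in units], dtype=float)
    probs /= probs.sum()
    draws = rng.choice(len(units), size=(scenario.n, 2), p=probs)
    out = []
    for i, j in draws:
        g = Genotype.of(units[i], units[j])
        out.append((g, phenotype_of(g)))
    return out


def simulate_cross(
    parent1: Genotype, parent2: Genotype, n_offspring: int, seed: int = 0
) -> List[Tuple[Genotype, MolecularPhenotype]]:
    """Each offspring receives one gamete from each parent."""
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    rng = np.random.default_rng(seed)
    out = []
    dists = []
    for parent in (parent1, parent2):
        gametes = gametes_of(parent)
        units = list(gametes)
        probs = np.array([float(p) for p in gametes.values()])
        dists.append((units, probs))
    for _ in range(n_offspring):
        picked = [
            units[rng.choice(len(units), p=probs)] for units, probs in dists
        ]
        g = Genotype.of(picked[0], picked[1])
        out.append((g, phenotype_of(g)))
    return out


_FEATURE_STATES = (ALLELES_1011, INTRON_TYPES, ALLELES_1016)


def simulate_clone_reads(
    genotype: Genotype,
    n_clones: int,
    error_rate: float = 0.0,
    seed: int = 0,
    specimen: str = "sim",
) -> List[CloneRecord]:
    """Sample clones uniformly from the haplotype slots present in the genotype.

    A duplicated unit contributes both of its haplotype slots.  With
    probability ``error_rate`` one feature of the sampled haplotype is flipped
    to the alternative state, mimicking PCR/cloning artifacts.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    slots = genotype.all_haplotypes()
    records = []
    for i in range(1, n_clones + 1):
        hap = slots[rng.integers(len(slots))]
        if error_rate and rng.random() < error_rate:
            feature = int(rng.integers(3))
            states = [hap.site1011, hap.intron, hap.site1016]
            current = states[feature]
            others = [s for s in _FEATURE_STATES[feature] if s != current]
            states[feature] = others[rng.integers(len(others))]
            hap = Haplotype(*states)
        records.append(CloneRecord(specimen=specimen, clone=f"c{i}", call=hap))
    return records


def simulate_qpcr(scenario: QpcrScenario) -> List[QpcrMeasurement]:
    """Gaussian-noise CT wells for every lineage/assay/pool/replicate.

    The target-gene CT drops by one cycle per doubling of template:
    ``ct_target = baseline + dct_offset - log2(copies / cn_ref_copies)`` with
    the reference lineage's copies as the calibration point, so a noiseless
    plate recovers every true copy number exactly.
    """
    rng = np.random.default_rng(scenario.seed)
    ref_copies = scenario.copies[scenario.reference_lineage]
    wells = []
    for lineage, copies in scenario.copies.items():
        for assay in range(1, scenario.n_assays + 1):
            for pool in range(1, scenario.n_pools + 1):
                pool_copies = copies
                if scenario.copy_jitter_sd:
                    pool_copies = copies * 2.0 ** rng.normal(0.0, scenario.copy_jitter_sd)
                shift = -math.log2(pool_copies / ref_copies)
                pool_id = f"{assay}.{pool}"
                for rep in range(1, scenario.n_replicates + 1):
                    ct_ref = scenario.ct_baseline + (
                        rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd else 0.0
                    )
                    ct_tgt = scenario.ct_baseline + scenario.dct_offset + shift + (
                        rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd else 0.0
                    )
                    wells.append(
                        QpcrMeasurement(lineage, assay, pool_id, rep, "reference", ct_ref)
                    )
                    wells.append(
                        QpcrMeasurement(lineage, assay, pool_id, rep, "target", ct_tgt)
                    )
    return wells


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def population_preset(name: str, n: int, seed: int = 0) -> PopulationScenario:
    """Named population scenarios.

    ``rockefeller``: monomorphic wild-type reference strain.
    ``ee``: fixed for the default duplicated unit (selected lineage).
    ``survey:<locality>[,<status>]``: random-union scenario at the haplotype
    frequencies estimated by gene counting from the bundled survey row.
    """
    key = name.strip().lower()
    if key == "rockefeller":
        return PopulationScenario({ChromosomeUnit.single(WILD_B): 1.0}, n=n, seed=seed)
    if key == "ee":
        return PopulationScenario({DEFAULT_DUPLICATION: 1.0}, n=n, seed=seed)
    if key.startswith("survey:"):
        spec = name.split(":", 1)[1]
        parts = [p.strip() for p in spec.split(",")]
        locality = parts[0]
        status = parts[1] if len(parts) > 1 else None
        sample = datasets.survey_sample(locality, status)
        freqs = estimate_haplotype_frequencies(sample)
        unit_freqs = {
            ChromosomeUnit.single(h): float(f) for h, f in freqs.freqs.items()
        }
        return PopulationScenario(unit_freqs, n=n, seed=seed)
    raise KeyError(f"unknown population preset: {name!r}")


def genotype_preset(name: str) -> Genotype:
    """Named genotypes: ``rockefeller`` (wild/wild), ``ee`` (dup/dup), ``hyb`` (their F1)."""
    wild = ChromosomeUnit.single(WILD_B)
    presets = {
        "rockefeller": Genotype.of(wild, wild),
        "ee": Genotype.of(DEFAULT_DUPLICATION, DEFAULT_DUPLICATION),
        "hyb": Genotype.of(wild, DEFAULT_DUPLICATION),
    }
    key = name.strip().lower()
    if key not in presets:
        raise KeyError(f"unknown genotype preset: {name!r}")
    return presets[key]


# ---------------------------------------------------------------------------
# CSV writers (the exact dialects the analysis readers consume)
# ---------------------------------------------------------------------------


def population_to_csv(
    individuals: Sequence[Tuple[Genotype, MolecularPhenotype]],
    path,
    locality: str = "simulated",
    status: str = "unclassified",
) -> None:
    """Aggregate simulated individuals into the phenotype-survey count dialect."""
    haps = sorted(
        {h for g, _ in individuals for h in g.all_haplotypes()}, key=lambda h: h.rank
    )
    categories = [ph.site_calls for ph in enumerate_phenotype_categories(haps)]
    counts = {k: 0 for k in categories}
    for _, ph in individuals:
        counts[ph.site_calls] = counts.get(ph.site_calls, 0) + 1
    row: Dict[str, object] = {
        "locality": locality,
        "status": status,
        "n": len(individuals),
    }
    for key, value in counts.items():
        row["count_" + category_column(key)] = value
    pd.DataFrame([row]).to_csv(path, index=False)


def cross_to_csv(
    offspring: Sequence[Tuple[Genotype, MolecularPhenotype]],
    path,
    cross_id: str = "sim",
    generation: str = "F1",
    parent1_phenotype: str = "",
    parent2_phenotype: str = "",
) -> None:
    counts = {"Ile/Ile": 0, "Ile/Met": 0, "Met/Met": 0}
    for _, ph in offspring:
        counts[ph.call1011] += 1
    pd.DataFrame(
        [
            {
                "cross_id": cross_id,
                "parent1_phenotype": parent1_phenotype,
                "parent2_phenotype": parent2_phenotype,
                "n_IleIle": counts["Ile/Ile"],
                "n_IleMet": counts["Ile/Met"],
                "n_MetMet": counts["Met/Met"],
                "generation": generation,
            }
        ]
    ).to_csv(path, index=False)


def clones_to_csv(records: Sequence[CloneRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "specimen": r.specimen,
                "clone": r.clone,
                "site1011": r.call.site1011,
                "intron": r.call.intron,
                "site1016": r.call.site1016,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def qpcr_to_csv(measurements: Sequence[QpcrMeasurement], path) -> None:
    pd.DataFrame(
        [
            {
                "lineage": m.lineage,
                "assay": m.assay,
                "pool": m.pool,
                "replicate": m.replicate,
                "gene": m.gene,
                "ct": m.ct,
            }
            for m in measurements
        ]
    ).to_csv(path, index=False)
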