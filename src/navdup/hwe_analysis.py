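"""Haplotype-frequency estimation and Hardy-Weinberg goodness-of-fit on phenotype tables.

The observable data are per-locality counts of two-site molecular-phenotype
categories.  When every category decodes to a unique haplotype pair (true for
the two- and three-haplotype single-copy models used here) the maximum-
likelihood haplotype frequencies are given directly by gene counting; the
general case falls back to an EM fixed point over the declared chromosome
units.  The fit test is a plain multinomial chi-square of observed counts
against random-union expectations with ``df = k - 1`` over the ``k`` declared
categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._util import largest_remainder
from .locus_model import (
    ChromosomeUnit,
    Genotype,
    Haplotype,
    MolecularPhenotype,
    MUT1011,
    MUT1016,
    WILD_B,
    category_column,
    enumerate_phenotype_categories,
    phenotype_of,
)

CategoryKey = Tuple[str, str]

#: Canonical six-category column order of the phenotype survey table.
CANONICAL_CATEGORIES: Tuple[CategoryKey, ...] = (
    ("Ile/Ile", "Val/Val"),
    ("Ile/Ile", "Val/Ile"),
    ("Ile/Ile", "Ile/Ile"),
    ("Ile/Met", "Val/Val"),
    ("Ile/Met", "Val/Ile"),
    ("Met/Met", "Val/Val"),
)

COUNT_COLUMNS = tuple("count_" + category_column(k) for k in CANONICAL_CATEGORIES)
FREQ_COLUMNS = tuple("freq_" + category_column(k) for k in CANONICAL_CATEGORIES)


class UndecodableCountsError(ValueError):
    """A phenotype category with non-zero count has no compatible genotype."""


def counts_from_frequencies(
    frequencies: Sequence[float], n: int, strict: bool = False
) -> List[int]:
    """Recover integer counts from published per-category proportions.

    Allocation is by largest remainder on ``freq * n`` so the result always
    sums to ``n`` exactly.  ``strict`` raises if any recovered count differs
    from its real-valued target by more than rounding can explain.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if any(f < 0 or f > 1 for f in frequencies):
        raise ValueError("proportions must lie in [0, 1]")
    total = sum(frequencies)
    if abs(total - 1.0) > 0.02:
        raise ValueError(f"proportions sum to {total:.4f}, expected 1 within 0.02")
    raw = [f * n for f in frequencies]
    counts = largest_remainder(raw, n)
    if strict:
        for r, c in zip(raw, counts):
            if abs(r - c) > 0.5 + 1e-9:
                raise ValueError(f"count {c} irreconcilable with frequency target {r:.3f}")
    return counts


@dataclass
class PopulationPhenotypeSample:
    """Phenotype-category counts for one locality sample."""

    locality: str
    status: str  # "R", "S" or "unclassified"
    n: int
    counts: Dict[CategoryKey, int]
    haplotypes: Tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if sum(self.counts.values()) != self.n:
            raise ValueError(
                f"counts sum to {sum(self.counts.values())}, expected n={self.n}"
            )
        declared = {
            ph.site_calls for ph in enumerate_phenotype_categories(self.haplotypes)
        }
        if set(self.counts) != declared:
            raise ValueError("count categories do not match the declared haplotype set")

    @property
    def categories(self) -> List[CategoryKey]:
        return [
            ph.site_calls for ph in enumerate_phenotype_categories(self.haplotypes)
        ]

    def count_vector(self) -> List[int]:
        return [self.counts[k] for k in self.categories]


@dataclass
class HaplotypeFrequencies:
    """Estimated proportions of haplotypes (or chromosome units)."""

    freqs: Dict[Hashable, float]

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, expected 1 within 1e-9")

    def __getitem__(self, key: Hashable) -> float:
        return self.freqs[key]


@dataclass
class HweResult:
    """Full per-sample analysis: estimates, expectations and the fit test."""

    sample: PopulationPhenotypeSample
    freqs: HaplotypeFrequencies
    expected: Dict[CategoryKey, float]
    chi2: float
    df: int
    p: float


def _units_from(units_or_haps: Sequence) -> List[ChromosomeUnit]:
    out = []
    for u in units_or_haps:
        out.append(ChromosomeUnit.single(u) if isinstance(u, Haplotype) else u)
    return out


def _pair_category_map(
    units: Sequence[ChromosomeUnit],
) -> Dict[CategoryKey, List[Tuple[int, int]]]:
    """Category key -> list of compatible unordered unit-pair indices."""
    mapping: Dict[CategoryKey, List[Tuple[int, int]]] = {}
    for i in range(len(units)):
        for j in range(i, len(units)):
            key = phenotype_of(Genotype.of(units[i], units[j])).site_calls
            mapping.setdefault(key, []).append((i, j))
    return mapping


def gene_counting(
    counts: Mapping[CategoryKey, int], units_or_haps: Sequence
) -> HaplotypeFrequencies:
    """Direct ML estimate when each category decodes to a unique unit pair."""
    units = _units_from(units_or_haps)
    mapping = _pair_category_map(units)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("all-zero counts")
    alloc = np.zeros(len(units))
    for key, c in counts.items():
        pairs = mapping.get(key, [])
        if not pairs:
            if c > 0:
                raise UndecodableCountsError(f"no genotype yields category {key}")
            continue
        if len(pairs) > 1:
            raise UndecodableCountsError(
                f"category {key} is compatible with {len(pairs)} genotypes; use EM"
            )
        i, j = pairs[0]
        alloc[i] += c
        alloc[j] += c
    freqs = alloc / (2 * n)
    keys = [u.haplotypes[0] if not u.is_duplicated else u for u in units]
    return HaplotypeFrequencies(dict(zip(keys, freqs)))


def em_frequencies(
    counts: Mapping[CategoryKey, int],
    units_or_haps: Sequence,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> HaplotypeFrequencies:
    """EM fixed point for unit frequencies under random union of units.

    Uniform initialisation; converges when the largest frequency change drops
    below ``tol``.  With a uniquely decodable category map this lands on the
    gene-counting estimate after one iteration.
    """
    units = _units_from(units_or_haps)
    mapping = _pair_category_map(units)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("all-zero counts")
    for key, c in counts.items():
        if c > 0 and key not in mapping:
            raise UndecodableCountsError(f"no genotype yields category {key}")
    k = len(units)
    p = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        alloc = np.zeros(k)
        for key, c in counts.items():
            if c == 0:
                continue
            pairs = mapping[key]
            weights = np.array(
                [(1.0 if i == j else 2.0) * p[i] * p[j] for i, j in pairs]
            )
            total = weights.sum()
            if total == 0:
                weights = np.ones(len(pairs))
                total = float(len(pairs))
            for (i, j), w in zip(pairs, weights):
                share = c * w / total
                alloc[i] += share
                alloc[j] += share
        new = alloc / (2 * n)
        delta = np.abs(new - p).max()
        p = new
        if delta < tol:
            break
    keys = [u.haplotypes[0] if not u.is_duplicated else u for u in units]
    return HaplotypeFrequencies(dict(zip(keys, p)))


def estimate_haplotype_frequencies(
    sample: PopulationPhenotypeSample,
    units: Optional[Sequence] = None,
) -> HaplotypeFrequencies:
    """Haplotype/unit frequency estimate for one sample.

    Defaults to the single-copy model over the sample's declared haplotypes,
    where gene counting applies; any other declared unit set goes through EM.
    """
    if units is None:
        units = list(sample.haplotypes)
    units = _units_from(units)
    mapping = _pair_category_map(units)
    unique = all(len(pairs) == 1 for pairs in mapping.values())
    if unique:
        return gene_counting(sample.counts, units)
    return em_frequencies(sample.counts, units)


def expected_phenotype_frequencies(
    freqs: Union[HaplotypeFrequencies, Mapping[Hashable, float]],
) -> Dict[CategoryKey, float]:
    """Random-union expected category proportions: hom ``p_i^2``, het ``2 p_i p_j``."""
    mapping = freqs.freqs if isinstance(freqs, HaplotypeFrequencies) else dict(freqs)
    units = _units_from(list(mapping.keys()))
    p = list(mapping.values())
    expected: Dict[CategoryKey, float] = {}
    for i in range(len(units)):
        for j in range(i, len(units)):
            key = phenotype_of(Genotype.of(units[i], units[j])).site_calls
            w = p[i] * p[j] if i == j else 2 * p[i] * p[j]
            expected[key] = expected.get(key, 0.0) + w
    return expected


def hwe_chi_square(
    observed: Sequence[int], expected: Sequence[float], n: int
) -> Tuple[float, int, float]:
    """Multinomial goodness-of-fit of counts against expected proportions.

    Categories with zero expectation and zero observation contribute nothing
    but still count toward ``df = k - 1``.  A zero expectation with a positive
    observation yields an infinite statistic (with a warning) rather than an
    exception.
    """
    if len(observed) != len(expected):
        raise ValueError("observed and expected must have the same length")
    k = len(observed)
    if k < 2:
        raise ValueError("need at least two categories")
    if sum(observed) != n:
        raise ValueError("observed counts must sum to n")
    chi2 = 0.0
    for o, e in zip(observed, expected):
        if e > 0:
            chi2 += (o - n * e) ** 2 / (n * e)
        elif o > 0:
            warnings.warn(
                "observed count in a category with zero expectation; "
                "chi-square is infinite",
                RuntimeWarning,
            )
            chi2 = float("inf")
            break
    df = k - 1
    p = 0.0 if np.isinf(chi2) else float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def analyze_population(
    sample: PopulationPhenotypeSample, units: Optional[Sequence] = None
) -> HweResult:
    """Chain estimate -> expectations -> chi-square for one sample."""
    freqs = estimate_haplotype_frequencies(sample, units=units)
    expected = expected_phenotype_frequencies(freqs)
    categories = sample.categories
    obs = [sample.counts[k] for k in categories]
    exp = [expected.get(k, 0.0) for k in categories]
    chi2, df, p = hwe_chi_square(obs, exp, sample.n)
    return HweResult(
        sample=sample,
        freqs=freqs,
        expected={k: expected.get(k, 0.0) for k in categories},
        chi2=chi2,
        df=df,
        p=p,
    )


def _infer_haplotypes(present: Sequence[CategoryKey]) -> Tuple[Haplotype, ...]:
    """Infer the declared haplotype set from which table columns are present."""
    present = set(present)
    haps = []
    if present & {("Ile/Ile", "Val/Val"), ("Ile/Ile", "Val/Ile"), ("Ile/Met", "Val/Val")}:
        haps.append(WILD_B)
    if present & {("Ile/Ile", "Val/Ile"), ("Ile/Ile", "Ile/Ile"), ("Ile/Met", "Val/Ile")}:
        haps.append(MUT1016)
    if present & {("Ile/Met", "Val/Val"), ("Ile/Met", "Val/Ile"), ("Met/Met", "Val/Val")}:
        haps.append(MUT1011)
    if not haps:
        raise ValueError("cannot infer a haplotype set from the present columns")
    return tuple(haps)


def sample_from_frequencies(
    locality: str,
    status: Optional[str],
    n: int,
    frequencies: Sequence[Optional[float]],
    strict: bool = False,
) -> PopulationPhenotypeSample:
    """Build a sample from the six-column frequency layout (None = absent column)."""
    keys = [k for k, f in zip(CANONICAL_CATEGORIES, frequencies) if f is not None]
    vals = [f for f in frequencies if f is not None]
    counts = counts_from_frequencies(vals, n, strict=strict)
    return PopulationPhenotypeSample(
        locality=locality,
        status=status or "unclassified",
        n=n,
        counts=dict(zip(keys, counts)),
        haplotypes=_infer_haplotypes(keys),
    )


def read_population_csv(path) -> List[PopulationPhenotypeSample]:
    """Read a phenotype survey CSV.

    Expected columns: ``locality,status,n`` plus either the six ``count_*``
    or the six ``freq_*`` category columns; blank cells mark categories that
    are structurally absent for that sample (reduced haplotype model).
    """
    df = pd.read_csv(path)
    use_counts = any(c in df.columns for c in COUNT_COLUMNS)
    columns = COUNT_COLUMNS if use_counts else FREQ_COLUMNS
    missing = [c for c in ("locality", "n") if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    samples = []
    for _, row in df.iterrows():
        n = int(row["n"])
        status = row.get("status")
        status = None if pd.isna(status) else str(status)
        cells = [
            (key, row[col])
            for key, col in zip(CANONICAL_CATEGORIES, columns)
            if col in df.columns and not pd.isna(row[col])
        ]
        keys = [k for k, _ in cells]
        if use_counts:
            counts = {k: int(v) for k, v in cells}
            samples.append(
                PopulationPhenotypeSample(
                    locality=str(row["locality"]),
                    status=status or "unclassified",
                    n=n,
                    counts=counts,
                    haplotypes=_infer_haplotypes(keys),
                )
            )
        else:
            samples.append(
                sample_from_frequencies(
                    str(row["locality"]), status, n,
                    [dict(cells).get(k) for k in CANONICAL_CATEGORIES],
                )
            )
    return samples


def results_frame(results: Sequence[HweResult]) -> pd.DataFrame:
    """Full-precision tidy frame of observed/expected proportions and the test."""
    rows = []
    for r in results:
        row: Dict[str, object] = {
            "locality": r.sample.locality,
            "status": r.sample.status,
            "n": r.sample.n,
        }
        for key in CANONICAL_CATEGORIES:
            col = category_column(key)
            if key in r.sample.counts:
                row["obs_" + col] = r.sample.counts[key] / r.sample.n
                row["exp_" + col] = r.expected[key]
            else:
                row["obs_" + col] = np.nan
                row["exp_" + col] = np.nan
        row["chi2"] = r.chi2
        row["df"] = r.df
        row["p"] = r.p
        rows.append(row)
    return pd.DataFrame(rows)
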