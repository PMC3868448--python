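"""Segregation analysis of crosses between wild-type and mutation-carrying parents.

Three competing parental constitutions explain an apparently heterozygous
(Ile/Met) parent: a conventional heterozygote over single units (H1), a
homozygote for the wild+mutant tandem duplication (H2a), or a heterozygote
carrying one single wild unit and one duplicated unit (H2b).  Offspring
phenotype distributions follow from convolving the parental gamete
distributions through the presence/absence masking operator; observed
offspring counts are compared with expectations via a two-sided Fisher exact
test on the observed-vs-expected 2x2 table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import largest_remainder
from .locus_model import (
    DEFAULT_DUPLICATION,
    ChromosomeUnit,
    Genotype,
    MUT1011,
    WILD_B,
    gametes_of,
    phenotype_of,
)

#: Site-1011 phenotype categories in table order.
SITE1011_CATEGORIES: Tuple[str, ...] = ("Ile/Ile", "Ile/Met", "Met/Met")

#: Default significance thresholds (code ``*``, ``**``, ``***``).
DEFAULT_ALPHAS: Tuple[float, float, float] = (0.05, 0.01, 0.001)

_WILD_SINGLE = ChromosomeUnit.single(WILD_B)
_MUT_SINGLE = ChromosomeUnit.single(MUT1011)

#: Homozygous wild-type parent, common to all three hypotheses.
WILD_PARENT = Genotype.of(_WILD_SINGLE, _WILD_SINGLE)


@dataclass(frozen=True)
class CrossHypothesis:
    """A labelled parental constitution for an Ile/Ile x Ile/Met cross."""

    label: str
    parent1: Genotype
    parent2: Genotype


def standard_hypotheses(
    duplication: ChromosomeUnit = DEFAULT_DUPLICATION,
) -> List[CrossHypothesis]:
    """H1 (no duplication), H2a (duplication homozygote), H2b (duplication heterozygote)."""
    return [
        CrossHypothesis("H1", WILD_PARENT, Genotype.of(_WILD_SINGLE, _MUT_SINGLE)),
        CrossHypothesis("H2a", WILD_PARENT, Genotype.of(duplication, duplication)),
        CrossHypothesis("H2b", WILD_PARENT, Genotype.of(_WILD_SINGLE, duplication)),
    ]


def offspring_phenotype_distribution(
    parent1: Genotype, parent2: Genotype
) -> Dict[str, Fraction]:
    """Distribution of the site-1011 call among offspring (exact rationals)."""
    dist: Dict[str, Fraction] = {}
    for u1, q1 in gametes_of(parent1).items():
        for u2, q2 in gametes_of(parent2).items():
            call = phenotype_of(Genotype.of(u1, u2)).call1011
            dist[call] = dist.get(call, Fraction(0)) + q1 * q2
    assert sum(dist.values()) == 1
    return dist


def expected_offspring(
    hypothesis: CrossHypothesis, n: int
) -> Tuple[Dict[str, float], Dict[str, int]]:
    """Expected offspring counts under a hypothesis, real-valued and integer-rendered.

    Integer rendering uses largest remainder so the integers sum to ``n``
    exactly (the form in which expectations are tabulated and tested).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    dist = offspring_phenotype_distribution(hypothesis.parent1, hypothesis.parent2)
    real = {c: float(dist.get(c, Fraction(0))) * n for c in SITE1011_CATEGORIES}
    ints = largest_remainder([real[c] for c in SITE1011_CATEGORIES], n)
    return real, dict(zip(SITE1011_CATEGORIES, ints))


def fisher_exact_2x2(table: Sequence[Sequence[int]], rel_tol: float = 1e-12) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability method).

    Sums hypergeometric point probabilities not exceeding that of the observed
    table, with a relative tolerance on the comparison to absorb floating-point
    ties.  A zero margin makes the table degenerate: p = 1 with a warning.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if 0 in (r1, r2, c1, c2):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", RuntimeWarning)
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + rel_tol)].sum())
    if p > 1.0 - 1e-9:  # absorb float summation error when the whole support is included
        return 1.0
    return p


def significance_code(p: float, alphas: Sequence[float] = DEFAULT_ALPHAS) -> str:
    """Star code for a p-value: ``***``/``**``/``*`` below the three thresholds, else ``NS``."""
    a1, a2, a3 = sorted(alphas, reverse=True)
    if p < a3:
        return "***"
    if p < a2:
        return "**"
    if p < a1:
        return "*"
    return "NS"


@dataclass
class CrossObservation:
    """Observed site-1011 phenotype counts among the offspring of one cross."""

    cross_id: str
    observed: Dict[str, int]
    generation: str = "F1"
    parent1_phenotype: Optional[str] = None
    parent2_phenotype: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = set(self.observed) - set(SITE1011_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown phenotype categories: {unknown}")
        if any(v < 0 for v in self.observed.values()):
            raise ValueError("counts must be non-negative")
        if self.n <= 0:
            raise ValueError("need at least one offspring")

    @property
    def n(self) -> int:
        return sum(self.observed.values())

    def vector(self) -> List[int]:
        return [self.observed.get(c, 0) for c in SITE1011_CATEGORIES]


@dataclass
class HypothesisTest:
    """One hypothesis evaluated against one cross."""

    label: str
    expected_real: Dict[str, float]
    expected_int: Dict[str, int]
    p: float
    code: str


@dataclass
class CrossVerdict:
    """All hypothesis tests for one cross, plus which hypotheses survive."""

    cross_id: str
    generation: str
    observed: Dict[str, int]
    tests: List[HypothesisTest]

    @property
    def not_rejected(self) -> List[str]:
        return [t.label for t in self.tests if t.code == "NS"]


def _observed_vs_expected_table(
    observed: Sequence[int], expected: Sequence[int]
) -> List[List[int]]:
    """Collapse a 2xk observed/expected layout to the 2x2 Fisher input.

    Categories empty in both rows are dropped; should more than two remain,
    the first is contrasted against the pooled rest.
    """
    keep = [i for i in range(len(observed)) if observed[i] + expected[i] > 0]
    if len(keep) < 2:
        # all counts in one category: no contrast to test
        return [[sum(observed), 0], [sum(expected), 0]]
    if len(keep) > 2:
        first = keep[0]
        return [
            [observed[first], sum(observed[i] for i in keep[1:])],
            [expected[first], sum(expected[i] for i in keep[1:])],
        ]
    i, j = keep
    return [[observed[i], observed[j]], [expected[i], expected[j]]]


def classify_cross(
    observation: CrossObservation,
    hypotheses: Optional[Sequence[CrossHypothesis]] = None,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> CrossVerdict:
    """Fisher-test the observed offspring against each hypothesis's expectation."""
    if hypotheses is None:
        hypotheses = standard_hypotheses()
    obs = observation.vector()
    tests = []
    for hyp in hypotheses:
        real, ints = expected_offspring(hyp, observation.n)
        table = _observed_vs_expected_table(
            obs, [ints[c] for c in SITE1011_CATEGORIES]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = fisher_exact_2x2(table)
        tests.append(HypothesisTest(hyp.label, real, ints, p, significance_code(p, alphas)))
    return CrossVerdict(
        cross_id=observation.cross_id,
        generation=observation.generation,
        observed=dict(observation.observed),
        tests=tests,
    )


def f2_segregation_test(
    observation: CrossObservation,
    duplication: ChromosomeUnit = DEFAULT_DUPLICATION,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> CrossVerdict:
    """Test F2 offspring against the 1:3 expectation of duplication-heterozygote parents.

    Both parents are modelled as single-wild / duplicated, so the expected
    F2 site-1011 split is 0.25 Ile/Ile : 0.75 Ile/Met.
    """
    parent = Genotype.of(_WILD_SINGLE, duplication)
    hyp = CrossHypothesis("F2(dup het x dup het)", parent, parent)
    return classify_cross(observation, hypotheses=[hyp], alphas=alphas)


def read_cross_csv(path) -> List[CrossObservation]:
    """Read cross observations: ``cross_id,parent1_phenotype,parent2_phenotype,
    n_IleIle,n_IleMet,n_MetMet,generation``."""
    df = pd.read_csv(path)
    required = ["cross_id", "n_IleIle", "n_IleMet"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    out = []
    for _, row in df.iterrows():
        observed = {
            "Ile/Ile": int(row["n_IleIle"]),
            "Ile/Met": int(row["n_IleMet"]),
            "Met/Met": int(row.get("n_MetMet", 0) or 0),
        }
        out.append(
            CrossObservation(
                cross_id=str(row["cross_id"]),
                observed=observed,
                generation=str(row.get("generation", "F1") or "F1"),
                parent1_phenotype=row.get("parent1_phenotype"),
                parent2_phenotype=row.get("parent2_phenotype"),
            )
        )
    return out


def verdicts_frame(verdicts: Sequence[CrossVerdict]) -> pd.DataFrame:
    """Tidy frame: one row per cross, per-hypothesis expectations, p and code."""
    rows = []
    for v in verdicts:
        row: Dict[str, object] = {
            "cross_id": v.cross_id,
            "generation": v.generation,
            "n": sum(v.observed.values()),
        }
        for c in SITE1011_CATEGORIES:
            row["obs_" + c.replace("/", "")] = v.observed.get(c, 0)
        for t in v.tests:
            for c in SITE1011_CATEGORIES:
                row[f"{t.label}_exp_{c.replace('/', '')}"] = t.expected_int[c]
            row[f"{t.label}_p"] = t.p
            row[f"{t.label}_code"] = t.code
        row["not_rejected"] = ";".join(v.not_rejected)
        rows.append(row)
    return pd.DataFrame(rows)
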