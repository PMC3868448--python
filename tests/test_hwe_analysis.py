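"""Tests for haplotype-frequency estimation and the Hardy-Weinberg fit test."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navdup import datasets
from navdup.hwe_analysis import (
    CANONICAL_CATEGORIES,
    HaplotypeFrequencies,
    PopulationPhenotypeSample,
    UndecodableCountsError,
    analyze_population,
    counts_from_frequencies,
    em_frequencies,
    estimate_haplotype_frequencies,
    expected_phenotype_frequencies,
    gene_counting,
    hwe_chi_square,
    read_population_csv,
    sample_from_frequencies,
)
from navdup.locus_model import MUT1011, MUT1016, WILD_B

THREE_HAP = (WILD_B, MUT1016, MUT1011)
TWO_HAP = (WILD_B, MUT1011)

SIX_KEYS = list(CANONICAL_CATEGORIES)
THREE_KEYS = [
    ("Ile/Ile", "Val/Val"),
    ("Ile/Met", "Val/Val"),
    ("Met/Met", "Val/Val"),
]


def make_sample(counts, haplotypes, locality="test", status="unclassified"):
    keys = SIX_KEYS if len(counts) == 6 else THREE_KEYS
    return PopulationPhenotypeSample(
        locality=locality,
        status=status,
        n=sum(counts),
        counts=dict(zip(keys, counts)),
        haplotypes=haplotypes,
    )


class TestCountsFromFrequencies:
    def test_six_category_row(self):
        # frozen oracle: round each freq*n and check the sum by hand
        assert counts_from_frequencies((0.056, 0, 0.222, 0.500, 0.222, 0), 18) == [
            1, 0, 4, 9, 4, 0,
        ]

    def test_two_haplotype_row(self):
        assert counts_from_frequencies((0.900, 0.100, 0), 20) == [18, 2, 0]

    def test_trivial_monomorphic(self):
        assert counts_from_frequencies((1.0, 0), 5) == [5, 0]

    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            counts_from_frequencies((0.5, 0.4), 10)

    def test_strict_mode_flags_irreconcilable(self):
        # 0.30*10 = 3 and 0.70*10 = 7 are fine
        assert counts_from_frequencies((0.3, 0.7), 10, strict=True) == [3, 7]

    @given(
        st.lists(st.integers(min_value=0, max_value=40), min_size=2, max_size=6).filter(
            lambda c: sum(c) > 0
        )
    )
    def test_roundtrip_from_exact_proportions(self, counts):
        n = sum(counts)
        freqs = [c / n for c in counts]
        assert counts_from_frequencies(freqs, n) == counts


class TestGeneCounting:
    def test_three_haplotype_row(self):
        # by-hand gene counting: freq = (2*hom + sum het)/2n
        freqs = gene_counting(dict(zip(SIX_KEYS, [1, 0, 4, 9, 4, 0])), THREE_HAP)
        assert freqs[WILD_B] == pytest.approx(11 / 36)
        assert freqs[MUT1016] == pytest.approx(12 / 36)
        assert freqs[MUT1011] == pytest.approx(13 / 36)

    def test_two_haplotype_row(self):
        freqs = gene_counting(dict(zip(THREE_KEYS, [4, 12, 0])), TWO_HAP)
        assert freqs[WILD_B] == pytest.approx(0.625)
        assert freqs[MUT1011] == pytest.approx(0.375)

    def test_monomorphic(self):
        freqs = gene_counting({("Ile/Ile", "Val/Val"): 20}, (WILD_B,))
        assert freqs[WILD_B] == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gene_counting(dict(zip(THREE_KEYS, [0, 0, 0])), TWO_HAP)

    def test_undecodable_category_rejected(self):
        with pytest.raises(UndecodableCountsError):
            gene_counting({("Met/Met", "Val/Val"): 5}, (WILD_B,))


class TestEstimateFrequencies:
    def test_defaults_to_gene_counting(self):
        sample = make_sample([1, 0, 4, 9, 4, 0], THREE_HAP)
        freqs = estimate_haplotype_frequencies(sample)
        assert freqs[WILD_B] == pytest.approx(11 / 36)

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(st.integers(min_value=0, max_value=30), min_size=6, max_size=6).filter(
            lambda c: sum(c) > 0
        )
    )
    def test_em_equals_gene_counting_when_uniquely_decodable(self, counts):
        counts_map = dict(zip(SIX_KEYS, counts))
        gc = gene_counting(counts_map, THREE_HAP)
        em = em_frequencies(counts_map, THREE_HAP)
        for h in THREE_HAP:
            assert abs(gc[h] - em[h]) < 1e-9


class TestExpectedFrequencies:
    def test_three_haplotype_expectations_to_3dp(self):
        freqs = HaplotypeFrequencies({WILD_B: 11 / 36, MUT1016: 12 / 36, MUT1011: 13 / 36})
        exp = expected_phenotype_frequencies(freqs)
        cells = [exp[k] for k in SIX_KEYS]
        assert cells == pytest.approx(
            [0.094, 0.204, 0.111, 0.221, 0.240, 0.130], abs=1e-3
        )

    def test_two_haplotype_expectations(self):
        freqs = HaplotypeFrequencies({WILD_B: 0.65, MUT1011: 0.35})
        exp = expected_phenotype_frequencies(freqs)
        cells = [exp[k] for k in THREE_KEYS]
        assert cells == pytest.approx([0.423, 0.455, 0.123], abs=1e-3)

    def test_monomorphic(self):
        exp = expected_phenotype_frequencies(HaplotypeFrequencies({WILD_B: 1.0}))
        assert exp[("Ile/Ile", "Val/Val")] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1.0, allow_nan=False),
            min_size=3,
            max_size=3,
        )
    )
    def test_expectations_sum_to_one(self, weights):
        total = sum(weights)
        freqs = HaplotypeFrequencies(
            dict(zip(THREE_HAP, [w / total for w in weights]))
        )
        exp = expected_phenotype_frequencies(freqs)
        assert sum(exp.values()) == pytest.approx(1.0, abs=1e-9)


class TestChiSquare:
    def test_six_category_fit(self):
        freqs = gene_counting(dict(zip(SIX_KEYS, [1, 0, 4, 9, 4, 0])), THREE_HAP)
        exp = expected_phenotype_frequencies(freqs)
        chi2, df, p = hwe_chi_square(
            [1, 0, 4, 9, 4, 0], [exp[k] for k in SIX_KEYS], 18
        )
        assert round(chi2, 1) == 14.7
        assert df == 5
        assert p == pytest.approx(0.0119, abs=2e-4)

    def test_near_monomorphic_row(self):
        freqs = gene_counting(dict(zip(THREE_KEYS, [15, 1, 0])), TWO_HAP)
        exp = expected_phenotype_frequencies(freqs)
        chi2, df, p = hwe_chi_square([15, 1, 0], [exp[k] for k in THREE_KEYS], 16)
        assert round(chi2, 2) == 0.02
        assert round(p, 4) == 0.9917

    def test_perfect_fit_gives_zero(self):
        chi2, df, p = hwe_chi_square([25, 50, 25], [0.25, 0.5, 0.25], 100)
        assert chi2 == 0.0
        assert p == 1.0

    def test_zero_expectation_with_observation_is_infinite(self):
        with pytest.warns(RuntimeWarning):
            chi2, df, p = hwe_chi_square([5, 5], [1.0, 0.0], 10)
        assert math.isinf(chi2)
        assert p == 0.0

    def test_zero_zero_category_counts_toward_df(self):
        chi2, df, p = hwe_chi_square([10, 0], [1.0, 0.0], 10)
        assert df == 1
        assert chi2 == 0.0


class TestAnalyzePopulation:
    @pytest.mark.parametrize(
        "locality,status,chi2_1dp,df",
        [
            ("Fortaleza", "R", 5.8, 2),
            ("Santa Rosa", None, 0.9, 2),
            ("Aparecida de Goiânia", "R", 14.7, 5),
        ],
    )
    def test_survey_rows(self, locality, status, chi2_1dp, df):
        result = analyze_population(datasets.survey_sample(locality, status))
        assert round(result.chi2, 1) == chi2_1dp
        assert result.df == df

    def test_monomorphic_sample_fits_perfectly(self):
        sample = PopulationPhenotypeSample(
            "mono", "unclassified", 20, {("Ile/Ile", "Val/Val"): 20, ("Ile/Met", "Val/Val"): 0, ("Met/Met", "Val/Val"): 0},
            TWO_HAP,
        )
        result = analyze_population(sample)
        assert result.chi2 == 0.0


class TestSampleValidation:
    def test_counts_must_sum_to_n(self):
        with pytest.raises(ValueError):
            PopulationPhenotypeSample(
                "x", "R", 10, dict(zip(THREE_KEYS, [1, 2, 3])), TWO_HAP
            )

    def test_category_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PopulationPhenotypeSample(
                "x", "R", 6, dict(zip(THREE_KEYS, [1, 2, 3])), THREE_HAP
            )


class TestCsvRoundtrip:
    def test_frequency_csv(self, tmp_path):
        path = tmp_path / "survey.csv"
        path.write_text(
            "locality,status,n,freq_IleIle_ValVal,freq_IleMet_ValVal,freq_MetMet_ValVal\n"
            "Fortaleza,R,16,0.250,0.750,0\n"
        )
        samples = read_population_csv(path)
        assert len(samples) == 1
        assert samples[0].count_vector() == [4, 12, 0]
        assert samples[0].haplotypes == (WILD_B, MUT1011)

    def test_count_csv_with_blank_columns(self, tmp_path):
        path = tmp_path / "survey.csv"
        path.write_text(
            "locality,status,n,count_IleIle_ValVal,count_IleIle_ValIle,count_IleIle_IleIle,"
            "count_IleMet_ValVal,count_IleMet_ValIle,count_MetMet_ValVal\n"
            "Ijui,unclassified,20,18,,,2,,0\n"
        )
        samples = read_population_csv(path)
        assert samples[0].count_vector() == [18, 2, 0]
        assert len(samples[0].categories) == 3
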