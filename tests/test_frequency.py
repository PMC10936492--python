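"""Allele/carrier/star-allele frequencies, Fisher comparison and BH FDR."""

import math

import numpy as np
import pytest

from pgxburden.frequency import (
    allele_frequency,
    carrier_frequency,
    compare_frequencies,
    compare_population_frequencies,
    counts_from_frequency,
    fdr_adjust,
    haplotype_star_frequency,
)
from pgxburden.model import (
    ParameterError,
    PhaseError,
    StarAlleleDefinition,
    UndefinedFrequencyError,
    VariantKey,
)
from pgxburden.synthetic import PopulationSpec, simulate_cohort

from conftest import make_matrix
from oracles import bh_oracle, fisher_two_sided_oracle


class TestAlleleFrequency:
    def test_direct_count_with_denominator(self):
        g = make_matrix([[(0, 1)], [(1, 1)]])
        rec = allele_frequency(g, g.variants[0], "G")
        assert rec.af == 0.75
        assert rec.n_chromosomes == 4

    def test_missing_calls_excluded_from_both_sides(self):
        g = make_matrix([[(0, 1)], [(-1, -1)], [(1, 1)]])
        rec = allele_frequency(g, g.variants[0], "G")
        assert rec.af == 0.75 and rec.n_chromosomes == 4

    def test_all_missing_is_an_error(self):
        g = make_matrix([[(-1, -1)], [(-1, -1)]])
        with pytest.raises(UndefinedFrequencyError):
            allele_frequency(g, g.variants[0], "G")

    def test_reference_allele_frequency_is_complement(self):
        g = make_matrix([[(0, 1)], [(1, 1)]])
        assert allele_frequency(g, g.variants[0], "A").af == 0.25

    def test_recovery_at_cohort_scale(self):
        # n=1029 individuals at the 25% frequency of a decreased-response
        # transporter variant: estimate lands within 2 points
        g, _ = simulate_cohort([PopulationSpec("IND", 1029, [0.25])], seed=42)
        rec = allele_frequency(g, g.variants[0], g.variants[0].alt, "IND")
        assert rec.n_chromosomes == 2058
        assert abs(rec.af - 0.25) < 0.02

    def test_unbiased_over_replicate_panels(self):
        g, _ = simulate_cohort([PopulationSpec("P", 500, [0.25] * 200)], seed=77)
        afs = [allele_frequency(g, v, v.alt, "P").af for v in g.variants]
        assert abs(np.mean(afs) - 0.25) < 0.005


class TestCarrierFrequency:
    def test_fraction_of_individuals_with_a_copy(self):
        g = make_matrix([[(0, 0)], [(0, 1)], [(1, 1)]])
        assert carrier_frequency(g, g.variants[0], "G") == pytest.approx(2 / 3)

    def test_monomorphic_reference_column(self):
        g = make_matrix([[(0, 0)], [(0, 0)]])
        assert carrier_frequency(g, g.variants[0], "G") == 0.0

    def test_hwe_closed_form_at_large_n(self):
        p = 0.0923
        g, _ = simulate_cohort([PopulationSpec("P", 100_000, [p])], seed=3)
        carrier = carrier_frequency(g, g.variants[0], g.variants[0].alt, "P")
        assert abs(carrier - (1 - (1 - p) ** 2)) < 0.01


class TestStarAlleles:
    def _two_site_matrix(self):
        # 2 samples = 4 haplotypes over 2 sites: (0,0), (1,0), (0,1), (1,1)
        return make_matrix(
            [
                [(0, 1), (0, 0)],
                [(0, 1), (0, 1)],
            ],
            variants=[
                VariantKey("10", 100, "C", "T", rsid="rsA"),
                VariantKey("10", 200, "G", "A", rsid="rsB"),
            ],
        )

    def test_single_site_definition(self):
        g = make_matrix([[(0, 0), (0, 0)], [(0, 1), (0, 0)]],
                        variants=self._two_site_matrix().variants)
        star2 = StarAlleleDefinition(
            "CYP2C9", "*2", ((g.variants[0], "T"),)
        )
        freqs = haplotype_star_frequency(g, [star2])
        assert freqs["*2"] == 0.25
        assert freqs["reference/other"] == 0.75

    def test_two_allele_definition_requires_both(self):
        g = self._two_site_matrix()
        star3 = StarAlleleDefinition(
            "CYP2C9", "*3", ((g.variants[0], "T"), (g.variants[1], "A"))
        )
        freqs = haplotype_star_frequency(g, [star3])
        # only haplotype (1,1) carries both required alleles
        assert freqs["*3"] == 0.25

    def test_first_match_wins_on_shared_defining_variant(self):
        g = self._two_site_matrix()
        star2 = StarAlleleDefinition("CYP2C9", "*2", ((g.variants[0], "T"),))
        star3 = StarAlleleDefinition(
            "CYP2C9", "*3", ((g.variants[0], "T"), (g.variants[1], "A"))
        )
        freqs = haplotype_star_frequency(g, [star2, star3])
        # exhaustive haplotype table: (0,0) other, (1,0) *2, (0,1) other,
        # (1,1) ambiguous -> first definition in input order (*2)
        assert freqs == {"*2": 0.5, "*3": 0.0, "reference/other": 0.5}
        # most-specific-first ordering resolves the ambiguity the other way
        freqs = haplotype_star_frequency(g, [star3, star2])
        assert freqs == {"*3": 0.25, "*2": 0.25, "reference/other": 0.5}

    def test_unphased_defining_site_names_the_sample(self):
        g = self._two_site_matrix()
        g.phased[1, 0] = False
        star2 = StarAlleleDefinition("CYP2C9", "*2", ((g.variants[0], "T"),))
        with pytest.raises(PhaseError, match="S1"):
            haplotype_star_frequency(g, [star2])


class TestFisherComparison:
    def test_symmetric_table_gives_p_one(self):
        _, p = compare_frequencies((5, 5), (5, 5))
        assert p == pytest.approx(1.0)

    def test_extreme_table_matches_closed_form(self):
        # both tails of the maximally skewed 10/10 table
        _, p = compare_frequencies((10, 0), (0, 10))
        expected = 2 * math.factorial(10) ** 2 / math.factorial(20)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_agrees_with_hypergeometric_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b == 0 or c + d == 0:
                continue
            _, p = compare_frequencies((int(a), int(b)), (int(c), int(d)))
            assert p == pytest.approx(
                fisher_two_sided_oracle(int(a), int(b), int(c), int(d)), abs=1e-10
            )

    def test_printed_population_difference_is_significant(self):
        # 12% vs 7% at 2058 chromosomes each (a TZD response variant against
        # the global average) must come out clearly significant
        ca = counts_from_frequency(0.12, 2058)
        cb = counts_from_frequency(0.07, 2058)
        oratio, p = compare_frequencies(ca, cb)
        assert p < 0.05
        assert oratio > 1

    def test_odds_ratio_edge_cases(self):
        assert np.isnan(compare_frequencies((0, 5), (0, 5))[0])
        assert np.isinf(compare_frequencies((5, 0), (0, 5))[0])

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            compare_frequencies((-1, 5), (2, 3))

    def test_null_calibration_of_rejection_rate(self):
        # both populations at one AF: Fisher should reject ~5% of 1000 variants
        g, _ = simulate_cohort(
            [
                PopulationSpec("A", 500, [0.3] * 1000),
                PopulationSpec("B", 500, [0.3] * 1000),
            ],
            seed=101,
        )
        rejections = 0
        for v in g.variants:
            fa = allele_frequency(g, v, v.alt, "A")
            fb = allele_frequency(g, v, v.alt, "B")
            _, p = compare_frequencies(
                counts_from_frequency(fa.af, fa.n_chromosomes),
                counts_from_frequency(fb.af, fb.n_chromosomes),
            )
            if p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07


class TestFdrAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_passes_through(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_closed_form_oracle_on_random_panels(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 60))
            np.testing.assert_allclose(fdr_adjust(p), bh_oracle(list(p)), atol=1e-12)

    def test_invariant_under_input_permutation(self):
        rng = np.random.default_rng(9)
        p = list(rng.uniform(0.001, 1, size=25)) + [0.5, 0.5]  # duplicates too
        q = fdr_adjust(p)
        perm = rng.permutation(len(p))
        q_perm = fdr_adjust([p[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-15)

    def test_q_monotone_in_sorted_p_order_and_at_least_p(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(1e-5, 1, size=200)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all()

    def test_rejects_out_of_domain_p(self):
        for bad in ([0.0, 0.5], [1.2], [-0.1]):
            with pytest.raises(ParameterError):
                fdr_adjust(bad)

    def test_thresholding_controls_false_discovery_on_null_panels(self):
        # 500 all-null panels of m=100: mean false-discovery proportion <= 0.07
        rng = np.random.default_rng(2024)
        fdp = []
        for _ in range(500):
            p = rng.uniform(size=100)
            p = np.clip(p, 1e-12, 1.0)
            rejected = fdr_adjust(p) < 0.05
            fdp.append(1.0 if rejected.any() else 0.0)
        assert np.mean(fdp) <= 0.05 + 0.02


class TestPopulationComparisonReport:
    def test_family_wide_q_and_significance_flags(self):
        g, _ = simulate_cohort(
            [
                PopulationSpec("IND", 300, [0.05, 0.6]),
                PopulationSpec("EUR", 300, [0.5, 0.6]),
            ],
            seed=55,
        )
        panel = [(v, v.alt) for v in g.variants]
        results = compare_population_frequencies(g, panel, "IND", alpha=0.05)
        assert len(results) == 2
        by_vid = {r.variant.vid: r for r in results}
        shifted = by_vid[g.variants[0].vid]
        null = by_vid[g.variants[1].vid]
        assert shifted.significant and shifted.q_value < 0.05
        assert not null.significant
        for r in results:
            assert r.q_value >= r.p_value - 1e-15
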