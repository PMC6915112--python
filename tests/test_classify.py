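"""Locus classification, parent patterns, segregation tests, annotation tallies.

Brute-force oracles here re-derive every quantity from first principles
(plain Python loops over Call objects) independently of the vectorised
implementation.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chisquare

from pseudohet.classify import (
    LocusClassValue,
    ParentPattern,
    classification_summary,
    classify_locus,
    classify_matrix,
    expand_annotation_counts,
    filter_missing_rate,
    parent_pattern,
    per_individual_stats,
    segregation_test,
    summarize_annotation,
)
from pseudohet.errors import ClassificationError, UsageError
from pseudohet.model import HET, HOM_ALT, HOM_REF, MISSING, Call

from conftest import make_matrix

CALL_STATES = [Call.hom("A"), Call.hom("G"), Call.het("A", "G"), Call.missing()]


def brute_force_class(calls, identical_requires_complete=True):
    """Independent re-derivation of the locus class from call categories."""
    het = [c for c in calls if c.is_het]
    if not het:
        return ("UNIFORM_HOMOZYGOUS", False)
    pairs = {c.alleles for c in het}
    if identical_requires_complete:
        ident = len(pairs) == 1 and len(het) == len(calls)
    else:
        ident = len(pairs) == 1 and all(c.is_het or c.is_missing for c in calls)
    return ("HETEROZYGOUS_ANY", ident)


class TestClassifyLocus:
    def test_exhaustive_oracle_equivalence(self):
        """Matches brute force on every call tuple of 1-4 individuals."""
        for n in range(1, 5):
            for combo in itertools.product(CALL_STATES, repeat=n):
                if all(c.is_missing for c in combo):
                    continue
                for strict in (True, False):
                    got = classify_locus(list(combo), identical_requires_complete=strict)
                    want = brute_force_class(combo, strict)
                    assert (got.value.value, got.identical_het_all) == want, combo

    def test_all_missing_is_uninformative(self):
        with pytest.raises(ClassificationError):
            classify_locus([Call.missing(), Call.missing()])

    def test_all_het_identical(self):
        got = classify_locus([Call.het("A", "T")] * 8)
        assert got.value is LocusClassValue.HETEROZYGOUS_ANY
        assert got.identical_het_all

    def test_missing_call_breaks_strict_identity_only(self):
        calls = [Call.het("A", "G")] * 7 + [Call.missing()]
        assert not classify_locus(calls).identical_het_all
        assert classify_locus(calls, identical_requires_complete=False).identical_het_all

    def test_all_hom_mixture_is_uniform_homozygous(self):
        calls = [Call.hom("T")] * 3 + [Call.hom("G")] * 5
        got = classify_locus(calls)
        assert got.value is LocusClassValue.UNIFORM_HOMOZYGOUS

    def test_vectorised_matrix_classification_agrees(self):
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 4, size=(40, 6)).astype(np.int8)
        codes[(codes == MISSING).all(axis=1), 0] = HET  # no uninformative rows
        m = make_matrix(codes)
        table = classify_matrix(m)
        for i in range(m.n_loci):
            want = brute_force_class(m.locus_calls(i))
            assert table.loc[i, "het_any"] == (want[0] == "HETEROZYGOUS_ANY")
            assert table.loc[i, "identical_het_all"] == want[1]


class TestFilterMissingRate:
    def test_strict_threshold_on_62_individuals(self):
        row_kept = [HET] * 53 + [MISSING] * 9  # 14.5% missing
        row_removed = [HET] * 52 + [MISSING] * 10  # 16.1% missing
        m = make_matrix([row_kept, row_removed])
        kept, n_removed = filter_missing_rate(m, 0.15)
        assert kept.n_loci == 1 and n_removed == 1
        assert kept.loci[0].position == 1

    def test_brute_force_oracle_on_random_fixture(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 4, size=(20, 10)).astype(np.int8)
        m = make_matrix(codes)
        kept, n_removed = filter_missing_rate(m, 0.3)
        want = [
            i for i in range(20)
            if sum(c.is_missing for c in m.locus_calls(i)) / 10 < 0.3
        ]
        assert [l.position for l in kept.loci] == [i + 1 for i in want]
        assert n_removed == 20 - len(want)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.integers(0, 4, size=(30, 8)).astype(np.int8))
        kept_counts = [
            filter_missing_rate(m, r)[0].n_loci for r in (0.0, 0.1, 0.25, 0.5, 1.0)
        ]
        assert kept_counts == sorted(kept_counts)

    def test_empty_matrix_passes_through(self):
        m = make_matrix(np.empty((0, 4), dtype=np.int8))
        kept, n_removed = filter_missing_rate(m)
        assert kept.n_loci == 0 and n_removed == 0


class TestParentPattern:
    @pytest.mark.parametrize(
        "f,m,want",
        [
            (HET, HET, ParentPattern.BOTH_HET_IDENTICAL),
            (HOM_REF, HET, ParentPattern.ONE_PARENT_HET),
            (HET, MISSING, ParentPattern.ONE_PARENT_HET),
            (HOM_REF, HOM_ALT, ParentPattern.PARENTS_HOM_DIFFERENT),
            (HOM_ALT, HOM_ALT, ParentPattern.PARENTS_HOM_SAME),
            (MISSING, MISSING, ParentPattern.OTHER),
            (HOM_REF, MISSING, ParentPattern.OTHER),
        ],
    )
    def test_partition(self, f, m, want):
        matrix = make_matrix([[f, m, HOM_REF, HOM_REF]])
        assert parent_pattern(0, matrix) is want

    def test_published_rows(self, table1_matrix):
        want = {
            "Scaffold32_7259": ParentPattern.BOTH_HET_IDENTICAL,
            "Scaffold19_12935": ParentPattern.ONE_PARENT_HET,
            "Scaffold311_1271": ParentPattern.PARENTS_HOM_DIFFERENT,
        }
        for i, locus in enumerate(table1_matrix.loci):
            if locus.id in want:
                assert parent_pattern(i, table1_matrix) is want[locus.id]


class TestPerIndividualStats:
    def test_direct_count(self):
        m = make_matrix([[HOM_REF, HOM_REF], [HET, HET], [HET, HOM_ALT], [MISSING, HOM_REF]])
        stats, _ = per_individual_stats(m)
        s = stats[0]
        assert (s.p_hom, s.p_het, s.p_missing) == (0.25, 0.5, 0.25)

    def test_proportions_partition_to_one(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.integers(0, 4, size=(17, 9)).astype(np.int8))
        stats, summary = per_individual_stats(m)
        for s in stats:
            assert abs(s.p_hom + s.p_het + s.p_missing - 1) < 1e-12
            assert s.n_hom + s.n_het + s.n_missing == m.n_loci
        assert set(summary) == {"p_hom", "p_het", "p_missing"}

    def test_brute_force_recount(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.integers(0, 4, size=(10, 5)).astype(np.int8))
        stats, _ = per_individual_stats(m)
        for j, s in enumerate(stats):
            calls = [m.call(i, j) for i in range(m.n_loci)]
            assert s.n_het == sum(c.is_het for c in calls)
            assert s.n_missing == sum(c.is_missing for c in calls)


class TestClassificationSummary:
    def test_all_identical_het(self):
        m = make_matrix(np.full((6, 4), HET, dtype=np.int8))
        s = classification_summary(m)
        assert s["frac_het_any"] == 1.0
        assert s["frac_identical_het_all"] == 1.0
        assert s["parent_pattern_counts"]["BOTH_HET_IDENTICAL"] == 6

    def test_class_fractions_partition(self):
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 4, size=(50, 6)).astype(np.int8)
        codes[(codes == MISSING).all(axis=1), 0] = HOM_REF
        s = classification_summary(make_matrix(codes))
        assert s["frac_het_any"] + s["frac_uniform_homozygous"] == pytest.approx(1.0)
        assert sum(s["parent_pattern_counts"].values()) == s["n_loci"]

    def test_published_table_classes(self, table1_matrix):
        """The five printed loci: 1 identical-het, 2 other het-any, 2 uniform-hom."""
        s = classification_summary(table1_matrix)
        assert s["n_het_any"] == 3
        assert s["n_identical_het_all_strict"] == 1
        assert s["n_uniform_homozygous"] == 2


class TestSegregationTest:
    def test_perfect_ratio(self):
        codes = [[HOM_REF, HOM_ALT] + [HOM_REF] * 30 + [HOM_ALT] * 30]
        r = segregation_test(0, make_matrix(codes))
        assert r.chi2 == 0 and r.p_value == 1 and r.consistent_1_1

    def test_six_to_zero_distortion(self):
        codes = [[HOM_REF, HOM_ALT] + [HOM_REF] * 6]
        r = segregation_test(0, make_matrix(codes))
        assert r.chi2 == pytest.approx(6.0)
        assert r.p_value == pytest.approx(0.01430588, abs=1e-6)
        assert not r.consistent_1_1

    def test_published_distorted_row(self, table1_matrix):
        """All shown offspring carry the male allele at Scaffold311 1271."""
        idx = [l.id for l in table1_matrix.loci].index("Scaffold311_1271")
        r = segregation_test(idx, table1_matrix)
        assert (r.n_allele_female, r.n_allele_male) == (0, 6)
        assert r.chi2 == pytest.approx(6.0)

    def test_untestable_when_no_hom_offspring(self):
        codes = [[HOM_REF, HOM_ALT] + [HET] * 4 + [MISSING] * 2]
        r = segregation_test(0, make_matrix(codes))
        assert r.untestable and r.consistent_1_1 is None
        assert r.n_het_offspring == 4 and r.n_missing_offspring == 2

    def test_requires_hom_different_parents(self):
        with pytest.raises(UsageError):
            segregation_test(0, make_matrix([[HET, HET, HOM_REF, HOM_ALT]]))

    def test_matches_closed_form_over_count_grid(self):
        """Pearson statistic equals scipy's two-cell goodness of fit, pairs <= 50."""
        for n_f in range(0, 51, 7):
            for n_m in range(0, 51, 7):
                if n_f + n_m == 0:
                    continue
                codes = [[HOM_REF, HOM_ALT] + [HOM_REF] * n_f + [HOM_ALT] * n_m]
                r = segregation_test(0, make_matrix(codes))
                want = chisquare([n_f, n_m])
                assert r.chi2 == pytest.approx(want.statistic)
                assert r.p_value == pytest.approx(want.pvalue)
                assert r.p_value == pytest.approx(float(chi2_dist.sf(r.chi2, 1)))


class TestSummarizeAnnotation:
    def test_published_class_totals(self, table2_sequences):
        tally = summarize_annotation(table2_sequences)
        assert tally.total == 6755
        assert tally.counts == {
            "Bacteria": 15, "Fungus": 11, "Rhodophyta": 27, "Zoology": 15, "Unknown": 6687,
        }
        assert tally.percentages["Unknown"] == 98.99
        assert tally.percentages["Rhodophyta"] == 0.40
        assert tally.total - tally.counts["Unknown"] == 68

    def test_counts_sum_to_total(self, table2_sequences):
        tally = summarize_annotation(table2_sequences)
        assert sum(tally.counts.values()) == tally.total
        assert sum(tally.percentages.values()) == pytest.approx(100, abs=0.05)

    def test_empty_table_warns(self):
        import pandas as pd

        with pytest.warns(UserWarning):
            tally = summarize_annotation(
                pd.DataFrame(columns=["sequence_id", "species", "class"])
            )
        assert tally.total == 0 and tally.counts == {}

    def test_expand_inverts_aggregation(self, table2_sequences):
        import pandas as pd

        counts = (
            table2_sequences.groupby(["class", "species"], sort=False)
            .size()
            .reset_index(name="count")
        )
        again = expand_annotation_counts(counts)
        assert len(again) == len(table2_sequences)
        assert (again["class"].value_counts() == table2_sequences["class"].value_counts()).all()
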