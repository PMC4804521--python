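"""Gene classification and expression-pattern statistics (TSI, CV, tests)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ctcfloops import (
    BedRecord,
    ChromSizes,
    GenomicInterval,
    classify_genes,
    compare_gene_classes,
    cv,
    enrichment_test,
    flag_outlier_datasets,
    tsi,
)


def gene(name, start, end, chrom="chr1"):
    return BedRecord(GenomicInterval(chrom, start, end), name)


LOOPS = [GenomicInterval("chr1", 10_000, 20_000), GenomicInterval("chr1", 50_000, 60_000)]


class TestClassifyGenes:
    def test_gene_inside_loop_body(self):
        (rec,) = classify_genes([gene("g", 12_000, 13_000)], LOOPS)
        assert rec.gene_class == "loop"

    def test_gene_in_flank_only(self):
        (rec,) = classify_genes([gene("g", 2_000, 3_000)], LOOPS)
        assert rec.gene_class == "flank"

    def test_gene_flanking_one_loop_but_inside_another_resolves_to_loop(self):
        # [20000, 30000) is the right flank of loop 1; place a second loop
        # there so the gene overlaps both a flank and a loop body
        loops = LOOPS + [GenomicInterval("chr1", 24_000, 28_000)]
        (rec,) = classify_genes([gene("g", 25_000, 26_000)], loops)
        assert rec.gene_class == "loop"

    def test_gene_on_loopless_chromosome_is_distal(self):
        (rec,) = classify_genes([gene("g", 100, 900, chrom="chr9")], LOOPS)
        assert rec.gene_class == "distal"

    def test_flanks_clipped_at_chromosome_end_not_discarded(self):
        sizes = ChromSizes({"chr1": 62_000})
        # right flank of loop 2 would span [60000, 70000); clipping keeps
        # [60000, 62000) so a gene there is still a flank gene
        (rec,) = classify_genes([gene("g", 61_000, 61_500)], LOOPS, sizes)
        assert rec.gene_class == "flank"

    def test_partition_is_disjoint_and_exhaustive_on_random_layouts(self, rng):
        for _ in range(100):
            n_loops = int(rng.integers(1, 6))
            loops = []
            for _ in range(n_loops):
                start = int(rng.integers(0, 900_000))
                loops.append(
                    GenomicInterval("chr1", start, start + int(rng.integers(500, 30_000)))
                )
            genes = [
                gene(f"g{i}", int(p), int(p) + int(rng.integers(100, 20_000)))
                for i, p in enumerate(rng.integers(0, 980_000, size=40))
            ]
            records = classify_genes(genes, loops)
            assert len(records) == len(genes)
            assert {r.gene_class for r in records} <= {"loop", "flank", "distal"}
            # cross-check the loop class against direct interval overlap
            for rec in records:
                in_loop = any(rec.interval.overlaps(l) for l in loops)
                assert (rec.gene_class == "loop") == in_loop


class TestTsi:
    @pytest.mark.parametrize(
        "vector,expected",
        [((1, 1, 1, 1), 0.0), ((0, 0, 0, 8), 1.0), ((2, 4, 8), 0.625)],
    )
    def test_closed_forms(self, vector, expected):
        assert tsi(vector) == pytest.approx(expected)

    def test_all_zero_vector_is_missing(self):
        assert math.isnan(tsi((0.0, 0.0, 0.0)))

    def test_single_cell_type_is_an_error(self):
        with pytest.raises(ValueError):
            tsi((5.0,))

    @given(
        st.lists(st.floats(0, 1e5), min_size=2, max_size=20).filter(
            lambda v: max(v) > 0
        ),
        st.floats(0.01, 100),
    )
    @settings(max_examples=300, deadline=None)
    def test_bounded_and_invariant_to_scaling_and_permutation(self, vector, c):
        value = tsi(vector)
        assert 0.0 <= value <= 1.0 + 1e-12
        assert tsi([c * v for v in vector]) == pytest.approx(value, abs=1e-9)
        assert tsi(sorted(vector)) == pytest.approx(value, abs=1e-9)


class TestCv:
    def test_constant_vector_is_zero(self):
        assert cv((3.0, 3.0, 3.0)) == 0.0

    def test_sample_sd_over_mean(self):
        # two-pass check: E=(2,4,6), sample SD 2, mean 4
        assert cv((2, 4, 6)) == pytest.approx(0.5)

    def test_zero_mean_is_missing(self):
        assert math.isnan(cv((0.0, 0.0)))

    @given(
        st.lists(st.floats(0.1, 1e4), min_size=2, max_size=15),
        st.floats(0.01, 100),
    )
    @settings(max_examples=300, deadline=None)
    def test_scale_invariant(self, vector, c):
        assert cv([c * v for v in vector]) == pytest.approx(cv(vector), rel=1e-6)


class TestCompareGeneClasses:
    def test_identical_samples(self):
        values = list(range(1, 30))
        result = compare_gene_classes(values, values)
        assert result["fold_change_of_medians"] == pytest.approx(1.0)
        assert result["p_value"] > 0.9

    def test_large_shift_is_significant(self, rng):
        a = rng.normal(100, 5, size=50)
        b = rng.normal(10, 5, size=50)
        for test in ("rank_sum", "welch_t"):
            assert compare_gene_classes(a, b, test)["p_value"] < 0.01

    def test_fold_change_of_medians(self):
        result = compare_gene_classes([3.0, 3.0, 3.0], [1.5, 1.5, 1.5])
        assert result["fold_change_of_medians"] == pytest.approx(2.0)

    def test_zero_denominator_median_gives_missing_fc_but_p(self):
        result = compare_gene_classes([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert math.isnan(result["fold_change_of_medians"])
        assert 0 <= result["p_value"] <= 1


def hypergeom_tail_oracle(overlap, universe, annotation, query):
    """P(X >= overlap) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for k in range(overlap, min(annotation, query) + 1):
        total += (
            math.comb(annotation, k)
            * math.comb(universe - annotation, query - k)
            / math.comb(universe, query)
        )
    return total


class TestEnrichment:
    def test_threefold_enrichment_example(self):
        universe = {f"g{i}" for i in range(100)}
        annotation = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(14, 24)}  # overlap 6 of 10
        result = enrichment_test(query, annotation, universe)
        assert result["fold_enrichment"] == pytest.approx(3.0)
        assert result["p_value"] == pytest.approx(
            hypergeom_tail_oracle(6, 100, 20, 10)
        )

    def test_overlap_at_expectation_has_moderate_p(self):
        universe = {f"g{i}" for i in range(100)}
        annotation = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(18, 28)}  # overlap 2 = expectation
        result = enrichment_test(query, annotation, universe)
        assert result["fold_enrichment"] == pytest.approx(1.0)
        assert 0.3 < result["p_value"] < 0.75

    def test_query_equals_annotation_gives_max_fold_and_minimal_tail(self):
        universe = {f"g{i}" for i in range(50)}
        annotation = {f"g{i}" for i in range(10)}
        result = enrichment_test(annotation, annotation, universe)
        assert result["fold_enrichment"] == pytest.approx(50 / 10)
        assert result["p_value"] == pytest.approx(
            hypergeom_tail_oracle(10, 50, 10, 10)
        )

    def test_agrees_with_pmf_tail_oracle_on_grid(self, rng):
        for _ in range(100):
            universe_n = int(rng.integers(10, 200))
            ann_n = int(rng.integers(1, universe_n + 1))
            query_n = int(rng.integers(1, universe_n + 1))
            universe = {f"g{i}" for i in range(universe_n)}
            annotation = set(rng.choice(sorted(universe), size=ann_n, replace=False))
            query = set(rng.choice(sorted(universe), size=query_n, replace=False))
            overlap = len(query & annotation)
            result = enrichment_test(query, annotation, universe)
            assert result["p_value"] == pytest.approx(
                hypergeom_tail_oracle(overlap, universe_n, ann_n, query_n), rel=1e-9
            )

    def test_empty_query_is_an_error(self):
        with pytest.raises(ValueError):
            enrichment_test(set(), {"a"}, {"a", "b"})

    def test_query_outside_universe_is_an_error(self):
        with pytest.raises(ValueError):
            enrichment_test({"x"}, {"a"}, {"a", "b"})


class TestOutlierFlagging:
    def test_documented_borderline_case_is_kept(self):
        # mean 77.5, sample SD exactly 45.0: 10 is not below 77.5 - 90
        labels = flag_outlier_datasets({"a": 100, "b": 100, "c": 100, "d": 10})
        assert labels == {"a": "kept", "b": "kept", "c": "kept", "d": "kept"}

    def test_all_equal_counts_all_kept(self):
        labels = flag_outlier_datasets({"a": 7, "b": 7, "c": 7})
        assert set(labels.values()) == {"kept"}

    def test_extreme_low_count_among_many_is_excluded(self, rng):
        counts = {f"d{i}": int(c) for i, c in enumerate(rng.normal(1000, 20, size=20))}
        counts["low"] = 5
        labels = flag_outlier_datasets(counts)
        assert labels["low"] == "excluded"
        assert all(v == "kept" for k, v in labels.items() if k != "low")

    def test_high_outliers_are_not_excluded(self):
        labels = flag_outlier_datasets({"a": 10, "b": 10, "c": 10, "d": 10_000})
        assert labels["d"] == "kept"

    def test_needs_three_datasets(self):
        with pytest.raises(ValueError):
            flag_outlier_datasets({"a": 1, "b": 2})
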