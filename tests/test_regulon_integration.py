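import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resnominate.errors import UndefinedFractionError, ValidationError
from resnominate.regulon_integration import (
    GeneSet,
    GenomicInterval,
    PromoterWindowSpec,
    VennCounts,
    adjust_family,
    cooccupancy_fraction,
    filter_candidates,
    hypergeom_enrichment,
    intersect_deg_sets,
    merge_intervals,
    overlap_percentage,
    peaks_to_genes,
    promoter_windows,
    read_bed,
    replicate_consensus,
    write_bed,
)

from .oracles import bitmap_consensus, bitmap_overlaps, hypergeom_tail, naive_set_overlap


def random_intervals(rng, n, length=10_000, max_width=300):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, length - max_width))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval("chr1", start, start + width))
    return out


class TestConsensus:
    def test_identical_replicates_give_merged_self(self, rng):
        peaks = random_intervals(rng, 30)
        assert replicate_consensus(peaks, peaks) == merge_intervals(peaks)

    def test_disjoint_replicates_empty(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 200, 300)]
        assert replicate_consensus(a, b) == []

    def test_matches_bitmap_oracle(self, rng):
        for _ in range(20):
            a = random_intervals(rng, int(rng.integers(1, 40)))
            b = random_intervals(rng, int(rng.integers(1, 40)))
            got = [(iv.start, iv.end) for iv in replicate_consensus(a, b)]
            assert got == bitmap_consensus(a, b, "chr1", 10_000)

    def test_commutative(self, rng):
        a, b = random_intervals(rng, 25), random_intervals(rng, 25)
        assert replicate_consensus(a, b) == replicate_consensus(b, a)

    def test_chromosomes_kept_separate(self):
        a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 0, 100)]
        b = [GenomicInterval("chr2", 50, 150)]
        assert replicate_consensus(a, b) == [GenomicInterval("chr2", 50, 100)]


interval_lists = st.lists(
    st.tuples(st.integers(0, 900), st.integers(1, 100)).map(
        lambda t: GenomicInterval("chr1", t[0], t[0] + t[1])
    ),
    min_size=1,
    max_size=30,
)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(a=interval_lists, b=interval_lists)
def test_consensus_property_bitmap_and_symmetry(a, b):
    """Consensus equals the bitmap AND of the two coverages, symmetrically."""
    got = [(iv.start, iv.end) for iv in replicate_consensus(a, b)]
    assert got == bitmap_consensus(a, b, "chr1", 1001)
    assert got == [(iv.start, iv.end) for iv in replicate_consensus(b, a)]


@settings(deadline=None, max_examples=60, derandomize=True)
@given(a=interval_lists)
def test_consensus_idempotent(a):
    assert replicate_consensus(a, a) == merge_intervals(a)


def test_interval_validation():
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", -5, 10)


def test_bed_round_trip_and_line_numbers(tmp_path):
    path = tmp_path / "peaks.bed"
    intervals = [GenomicInterval("chr1", 10, 50, "p1"), GenomicInterval("chr2", 0, 7)]
    write_bed(intervals, path)
    assert read_bed(path) == sorted(intervals)

    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t10\t50\nchr1\t90\t20\n")
    with pytest.raises(ValidationError, match=":2"):
        read_bed(bad)


class TestPromoterWindows:
    def tss(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])

    def test_window_arithmetic(self):
        windows = promoter_windows(self.tss([("g1", "chr1", 100_000, "+")]))
        assert windows["g1"] == GenomicInterval("chr1", 95_000, 105_001, "g1")

    def test_clipping_at_zero(self):
        windows = promoter_windows(self.tss([("g1", "chr1", 2000, "+")]))
        assert (windows["g1"].start, windows["g1"].end) == (0, 7001)

    def test_clipping_at_chrom_size(self):
        spec = PromoterWindowSpec(flank=5000, chrom_sizes={"chr1": 101_000})
        windows = promoter_windows(self.tss([("g1", "chr1", 100_000, "+")]), spec)
        assert windows["g1"].end == 101_000

    def test_negative_tss_rejected(self):
        with pytest.raises(ValidationError):
            promoter_windows(self.tss([("g1", "chr1", -5, "+")]))

    def test_windows_contain_tss_and_bounded_width(self, rng):
        rows = [(f"g{i}", "chr1", int(rng.integers(0, 10**7)), "+") for i in range(50)]
        for flank in (0, 100, 5000):
            windows = promoter_windows(self.tss(rows), PromoterWindowSpec(flank=flank))
            for (gene, _, tss, _) in rows:
                iv = windows[gene]
                assert iv.start <= tss < iv.end
                assert iv.length <= 2 * flank + 1


class TestPeaksToGenes:
    windows = {"g1": GenomicInterval("chr1", 1000, 2001, "g1")}

    def test_peak_inside_window_binds(self):
        bound = peaks_to_genes([GenomicInterval("chr1", 1500, 1600)], self.windows)
        assert bound.genes == {"g1"}

    def test_half_open_abutment_does_not_bind(self):
        bound = peaks_to_genes([GenomicInterval("chr1", 900, 1000)], self.windows)
        assert bound.genes == set()

    def test_single_base_overlap_binds(self):
        bound = peaks_to_genes([GenomicInterval("chr1", 2000, 2100)], self.windows)
        assert bound.genes == {"g1"}

    def test_unknown_chromosome_is_not_fatal(self):
        bound = peaks_to_genes([GenomicInterval("chrX", 1500, 1600)], self.windows)
        assert bound.genes == set()

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(15):
            peaks = random_intervals(rng, 40)
            windows = {
                f"g{i}": GenomicInterval("chr1", s, s + 500, f"g{i}")
                for i, s in enumerate(rng.integers(0, 9_000, size=25))
            }
            bound = peaks_to_genes(peaks, windows)
            naive = {
                g for g, w in windows.items()
                if any(w.overlaps(p) for p in peaks)
            }
            assert bound.genes == naive


class TestCooccupancy:
    def test_full_cover_is_one(self, rng):
        peaks = random_intervals(rng, 10)
        assert cooccupancy_fraction(peaks, [GenomicInterval("chr1", 0, 10_000)]) == 1.0

    def test_no_marks_is_zero(self, rng):
        assert cooccupancy_fraction(random_intervals(rng, 10), []) == 0.0

    def test_empty_peaks_undefined(self):
        with pytest.raises(UndefinedFractionError):
            cooccupancy_fraction([], [GenomicInterval("chr1", 0, 10)])

    def test_matches_bitmap_oracle(self, rng):
        for _ in range(15):
            peaks = random_intervals(rng, 30)
            marks = random_intervals(rng, 20)
            frac = cooccupancy_fraction(peaks, marks)
            flags = bitmap_overlaps(peaks, marks, "chr1", 10_000)
            assert frac == sum(flags) / len(flags)


class TestGeneSets:
    def test_unique_identifiers_enforced(self):
        with pytest.raises(ValidationError):
            GeneSet("dup", ["a", "a"])

    def test_disjoint_and_subset_overlaps(self):
        a = GeneSet("a", ["x", "y"])
        b = GeneSet("b", ["p", "q"])
        assert intersect_deg_sets(a, b).overlap == 0
        sub = GeneSet("sub", ["x"])
        assert intersect_deg_sets(sub, a).overlap == 1

    def test_matches_sorted_merge_oracle(self, rng):
        for _ in range(10):
            a = GeneSet("a", {f"g{i}" for i in rng.integers(0, 500, size=200)})
            b = GeneSet("b", {f"g{i}" for i in rng.integers(0, 500, size=200)})
            assert intersect_deg_sets(a, b).overlap == naive_set_overlap(a.genes, b.genes)


class TestPercentages:
    @pytest.mark.parametrize(
        "size_a,overlap,expected",
        [(7690, 1849, 24), (3969, 678, 17), (100, 0, 0)],
    )
    def test_rounded_percentages(self, size_a, overlap, expected):
        venn = VennCounts(size_a=size_a, size_b=10_000, overlap=overlap)
        assert overlap_percentage(venn, "A").rounded == expected

    def test_half_rounds_away_from_zero(self):
        venn = VennCounts(size_a=200, size_b=200, overlap=5)  # 2.5%
        assert overlap_percentage(venn, "A").rounded == 3

    def test_overlap_reconstructible_from_both_sides(self):
        venn = VennCounts(size_a=400, size_b=250, overlap=100)
        pa = overlap_percentage(venn, "A").percent
        pb = overlap_percentage(venn, "B").percent
        assert round(pa * venn.size_a / 100) == venn.overlap
        assert round(pb * venn.size_b / 100) == venn.overlap

    def test_zero_side_undefined(self):
        with pytest.raises(UndefinedFractionError):
            overlap_percentage(VennCounts(0, 5, 0), "A")


class TestHypergeometric:
    def test_complete_overlap_small_universe(self):
        """N=10, both sets of 5, overlap 5: p = 1/C(10,5) = 1/252."""
        res = hypergeom_enrichment(5, 5, 5, 10)
        assert res.p_value == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_enrichment(0, 8, 10, 20).p_value == pytest.approx(1.0)

    def test_matches_pmf_sum(self):
        assert hypergeom_enrichment(6, 8, 10, 20).p_value == pytest.approx(
            hypergeom_tail(6, 8, 10, 20), rel=1e-12
        )

    def test_monotone_decreasing_in_k(self):
        ps = [hypergeom_enrichment(k, 8, 10, 20).p_value for k in range(0, 9)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrichment(6, 5, 10, 20)
        with pytest.raises(ValidationError):
            hypergeom_enrichment(1, 25, 10, 20)

    def test_bh_adjustment_never_below_raw(self, rng):
        results = [
            hypergeom_enrichment(int(k), 50, 50, 500)
            for k in rng.integers(0, 30, size=12)
        ]
        adjust_family(results)
        for r in results:
            assert r.p_adjusted >= r.p_value
            assert r.p_adjusted <= 1.0


class TestCandidateFilter:
    def test_three_way_intersection(self):
        bound = GeneSet("bound", ["a", "b", "c", "d"])
        down_kd = GeneSet("kd", ["b", "c", "d", "e"])
        down_ref = GeneSet("ref", ["c", "d", "f"])
        candidates, intermediate = filter_candidates(bound, down_kd, down_ref)
        assert candidates.genes == {"c", "d"}
        assert intermediate.genes == {"b", "c", "d"}

    def test_empty_input_gives_empty_result(self):
        empty = GeneSet("e", [])
        full = GeneSet("f", ["a", "b"])
        candidates, _ = filter_candidates(full, empty, full)
        assert candidates.genes == set()
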