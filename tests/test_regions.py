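"""Region algebra: union, intersection, exclusion, sizes, gene counts.

Properties are checked against a brute-force bitmap oracle on a toy
genome; the bundled candidate-region dataset exercises the half-open size
convention on real published coordinates.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bulkmap.datasets import rice_candidate_regions
from bulkmap.regions import (GeneAnnotation, Region, count_genes, exclude,
                             intersect_tracks, read_bed, read_gff3,
                             region_report, total_gene_count, total_size_mb,
                             union_regions, write_bed)


def spans(regions):
    return sorted((r.chrom, r.start, r.end) for r in regions)


class TestRegionBasics:
    def test_size_from_half_open_bounds(self):
        assert Region("Chr1", 36_420_000, 37_240_000).size_mb == pytest.approx(0.82)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            Region("Chr1", 100, 100)

    def test_contains_half_open(self):
        r = Region("Chr1", 100, 200)
        assert r.contains("Chr1", 100) and not r.contains("Chr1", 200)


class TestUnion:
    def test_union_of_identical_sets_is_the_set(self):
        a = [Region("Chr1", 0, 10), Region("Chr2", 5, 9)]
        assert spans(union_regions(a, a)) == spans(a)

    def test_overlap_merges(self):
        got = union_regions([Region("Chr1", 0, 10)], [Region("Chr1", 5, 20)])
        assert spans(got) == [("Chr1", 0, 20)]

    def test_shared_interval_counted_once(self):
        table = rice_candidate_regions()
        ph = exclude(table["PH"], drop_chroms=["Chr2", "Chr7"])
        dh = exclude(table["DH"], drop_chroms=["Chr2", "Chr7"])
        merged = union_regions(ph, dh)
        chr1 = [r for r in merged if r.chrom == "Chr1"]
        assert spans(chr1) == [("Chr1", 36_420_000, 37_240_000)]


class TestIntersection:
    def test_idempotence(self):
        a = [Region("Chr1", 0, 10), Region("Chr3", 100, 300)]
        assert spans(intersect_tracks([a, a])) == spans(a)

    def test_cross_trait_chr7_overlap(self):
        got = intersect_tracks([[Region("Chr7", 27_310_000, 29_690_000)],
                                [Region("Chr7", 27_520_000, 29_690_000)]])
        assert spans(got) == [("Chr7", 27_520_000, 29_690_000)]
        assert total_size_mb(got) == pytest.approx(2.17)

    def test_disjoint_sets_empty(self):
        assert intersect_tracks([[Region("Chr1", 0, 10)],
                                 [Region("Chr1", 20, 30)]]) == []

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            intersect_tracks([[Region("Chr1", 0, 10)]])


class TestExclude:
    def test_drop_chromosome(self):
        ph = rice_candidate_regions()["PH"]
        assert len(exclude(ph, drop_chroms=["Chr7"])) == 4

    def test_subtract_splits(self):
        got = exclude([Region("Chr1", 0, 20)],
                      drop_intervals=[Region("Chr1", 5, 10)])
        assert spans(got) == [("Chr1", 0, 5), ("Chr1", 10, 20)]

    def test_absent_chromosome_noop(self):
        ph = rice_candidate_regions()["PH"]
        assert spans(exclude(ph, drop_chroms=["Chr99"])) == spans(ph)


class TestTotalSize:
    def test_empty(self):
        assert total_size_mb([]) == 0.0

    def test_union_bounded_by_sum(self):
        a = [Region("Chr1", 0, 1_000_000), Region("Chr1", 500_000, 2_000_000)]
        assert total_size_mb(union_regions(a)) < sum(r.size_mb for r in a)
        disjoint = [Region("Chr1", 0, 10), Region("Chr1", 20, 30)]
        assert total_size_mb(union_regions(disjoint)) == \
            pytest.approx(sum(r.size_mb for r in disjoint))


interval = st.tuples(st.integers(0, 99), st.integers(1, 20)).map(
    lambda t: (t[0] * 10_000, (t[0] + t[1]) * 10_000))
interval_set = st.lists(interval, min_size=1, max_size=8)


def bitmap(region_set, size=1_200_000, unit=10_000):
    mask = np.zeros(size // unit, dtype=bool)
    for s, e in region_set:
        mask[s // unit:e // unit] = True
    return mask


def as_regions(region_set):
    return [Region("Chr1", s, e) for s, e in region_set]


class TestAlgebraAgainstBitmapOracle:
    @given(a=interval_set, b=interval_set)
    @settings(max_examples=100, deadline=None)
    def test_union_and_commutativity(self, a, b):
        got_ab = union_regions(as_regions(a), as_regions(b))
        got_ba = union_regions(as_regions(b), as_regions(a))
        assert spans(got_ab) == spans(got_ba)
        assert bitmap([(r.start, r.end) for r in got_ab]).tolist() == \
            (bitmap(a) | bitmap(b)).tolist()

    @given(a=interval_set, b=interval_set)
    @settings(max_examples=100, deadline=None)
    def test_intersection(self, a, b):
        got = intersect_tracks([as_regions(a), as_regions(b)])
        assert bitmap([(r.start, r.end) for r in got]).tolist() == \
            (bitmap(a) & bitmap(b)).tolist()

    @given(a=interval_set, b=interval_set, c=interval_set)
    @settings(max_examples=50, deadline=None)
    def test_associativity(self, a, b, c):
        left = intersect_tracks([as_regions(a), as_regions(b), as_regions(c)])
        right = intersect_tracks(
            [as_regions(a),
             intersect_tracks([as_regions(b), as_regions(c)]) or
             [Region("ChrNull", 0, 1)]])
        assert spans(left) == spans(r for r in right if r.chrom == "Chr1")

    @given(a=interval_set, b=interval_set)
    @settings(max_examples=100, deadline=None)
    def test_subtraction(self, a, b):
        got = exclude(as_regions(a), drop_intervals=as_regions(b))
        assert bitmap([(r.start, r.end) for r in got]).tolist() == \
            (bitmap(a) & ~bitmap(b)).tolist()


class TestGeneCounting:
    def test_empty_annotation(self):
        got = count_genes([Region("Chr1", 0, 100)], GeneAnnotation([]))
        assert got[0].gene_count == 0

    def test_one_bp_overlap_counts(self):
        ann = GeneAnnotation([("g1", "Chr1", 100, 200)])
        got = count_genes([Region("Chr1", 150, 300)], ann)
        assert got[0].gene_count == 1

    def test_tiling_brute_force(self):
        # 10 genes tiling 1 Mb; region covering the first half catches 5
        ann = GeneAnnotation([(f"g{i}", "Chr1", i * 100_000, (i + 1) * 100_000)
                              for i in range(10)])
        region = Region("Chr1", 0, 500_000)
        brute = sum(1 for _, _, s, e in ann.records
                    if s < region.end and region.start < e)
        assert count_genes([region], ann)[0].gene_count == brute == 5

    def test_midpoint_mode(self):
        ann = GeneAnnotation([("g1", "Chr1", 100, 200)])
        assert count_genes([Region("Chr1", 140, 300)], ann,
                           mode="midpoint")[0].gene_count == 1
        assert count_genes([Region("Chr1", 160, 300)], ann,
                           mode="midpoint")[0].gene_count == 0

    def test_gene_spanning_two_regions_deduplicated_in_total(self):
        ann = GeneAnnotation([("g1", "Chr1", 90, 210)])
        regions = [Region("Chr1", 0, 100), Region("Chr1", 200, 300)]
        counted = count_genes(regions, ann)
        assert [r.gene_count for r in counted] == [1, 1]
        assert total_gene_count(regions, ann) == 1

    def test_gff3_reading(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "Chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneA\n"
            "Chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=geneA.1;Parent=geneA\n"
            "Chr2\tsrc\tgene\t51\t80\t.\t-\t.\tID=geneB\n")
        ann = read_gff3(gff)
        assert len(ann) == 2
        # GFF3 1-based inclusive converted to half-open
        assert ("geneA", "Chr1", 100, 200) in ann.records


class TestIO:
    def test_bed_round_trip(self, tmp_path):
        regions = [Region("Chr2", 100, 900), Region("Chr1", 0, 50)]
        path = tmp_path / "r.bed"
        write_bed(regions, path)
        assert spans(read_bed(path)) == spans(regions)

    def test_report_rounds_sizes(self):
        df = region_report([Region("Chr1", 36_420_000, 37_240_000, trait="PH")])
        assert df.loc[0, "size_mb"] == 0.82
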