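"""Expressed-region detection, region matrices and base classification."""

import numpy as np
import pytest

from covquant import (
    CoverageVector,
    GenomicInterval,
    annotate_regions,
    filter_regions_by_width,
    find_expressed_regions,
    region_base_coverage,
    region_coverage_matrix,
)
from conftest import regions_oracle


def region_tuples(regions):
    return [
        (r.interval.start, r.interval.end, r.value, r.area, r.cluster, r.cluster_length)
        for r in regions
    ]


class TestFindExpressedRegions:
    def test_toy_coverage_cutoff_2_gap_1(self, toy_cov):
        regions = find_expressed_regions(toy_cov, cutoff=2, max_cluster_gap=1)
        assert region_tuples(regions) == [
            (1, 5, 3.8, 19.0, 1, 5),
            (8, 8, 3.0, 3.0, 2, 7),
            (10, 11, 3.0, 6.0, 2, 7),
            (13, 14, 4.0, 8.0, 2, 7),
        ]

    def test_cutoff_above_max_gives_empty(self, toy_cov):
        assert find_expressed_regions(toy_cov, cutoff=5, max_cluster_gap=10) == []

    def test_strict_cutoff_excludes_equal_bases(self, toy_cov):
        # bases 6,7,15 have coverage exactly 2 and must not be expressed
        strict = find_expressed_regions(toy_cov, 2, 0)
        covered = {b for r in strict for b in range(r.interval.start, r.interval.end + 1)}
        assert 6 not in covered and 7 not in covered and 15 not in covered
        lenient = find_expressed_regions(toy_cov, 2, 0, strict=False)
        covered_ge = {
            b for r in lenient for b in range(r.interval.start, r.interval.end + 1)
        }
        assert {6, 7, 15} <= covered_ge

    def test_flanking_bases_below_cutoff(self, toy_cov):
        dense = toy_cov.to_dense()
        for r in find_expressed_regions(toy_cov, 2, 1):
            assert (dense[r.interval.start - 1 : r.interval.end] > 2).all()
            if r.interval.start > 1:
                assert dense[r.interval.start - 2] <= 2
            if r.interval.end < toy_cov.length:
                assert dense[r.interval.end] <= 2

    def test_index_fields_equal_genomic_coordinates(self, toy_cov):
        for r in find_expressed_regions(toy_cov, 2, 1):
            assert r.index_start == r.interval.start
            assert r.index_end == r.interval.end

    def test_matches_naive_base_scan_on_random_tracks(self):
        rng = np.random.default_rng(202609)
        for _ in range(150):
            dense = rng.integers(0, 8, size=int(rng.integers(10, 600)))
            cutoff = float(rng.integers(0, 6))
            gap = int(rng.integers(0, 12))
            cv = CoverageVector.from_dense("c", dense)
            got = region_tuples(find_expressed_regions(cv, cutoff, gap))
            want = [
                (o["start"], o["end"], o["value"], o["area"], o["cluster"],
                 o["cluster_length"])
                for o in regions_oracle(dense, cutoff, gap)
            ]
            assert got == pytest.approx(want)

    def test_raising_cutoff_shrinks_coverage_monotonically(self):
        rng = np.random.default_rng(8)
        dense = rng.integers(0, 10, size=500)
        cv = CoverageVector.from_dense("c", dense)
        prev_bases = None
        for cutoff in range(0, 10):
            regions = find_expressed_regions(cv, cutoff, 5)
            bases = set()
            for r in regions:
                bases.update(range(r.interval.start, r.interval.end + 1))
            if prev_bases is not None:
                assert bases <= prev_bases
            prev_bases = bases

    def test_cluster_gap_partition(self):
        rng = np.random.default_rng(17)
        dense = rng.integers(0, 4, size=800)
        cv = CoverageVector.from_dense("c", dense)
        gap = 7
        regions = find_expressed_regions(cv, 1, gap)
        for a, b in zip(regions, regions[1:]):
            d = b.interval.start - a.interval.end - 1
            if a.cluster == b.cluster:
                assert d <= gap
            else:
                assert d > gap
                assert b.cluster == a.cluster + 1


class TestFilterRegionsByWidth:
    def test_toy_min_width_2(self, toy_cov):
        regions = find_expressed_regions(toy_cov, 2, 1)
        kept = filter_regions_by_width(regions, 2)
        assert [(r.interval.start, r.interval.end) for r in kept] == [
            (1, 5), (10, 11), (13, 14)
        ]

    def test_min_width_1_is_identity(self, toy_cov):
        regions = find_expressed_regions(toy_cov, 2, 1)
        assert filter_regions_by_width(regions, 1) == regions

    def test_min_width_above_all_empties(self, toy_cov):
        regions = find_expressed_regions(toy_cov, 2, 1)
        assert filter_regions_by_width(regions, 100) == []

    def test_inclusive_boundary(self, toy_cov):
        regions = find_expressed_regions(toy_cov, 2, 1)
        widths = [r.width for r in filter_regions_by_width(regions, 5)]
        assert widths == [5]  # "at least" keeps the width-5 region


class TestRegionCoverageMatrix:
    def test_single_sample_column_equals_areas(self, toy):
        cov = toy.coverage()
        regions = find_expressed_regions(cov["seq"], 2, 1)
        mat = region_coverage_matrix(regions, {"toy": cov})
        assert mat.values[:, 0].tolist() == [19, 3, 6, 8]
        assert mat.values[:, 0].tolist() == [r.area for r in regions]

    def test_zero_coverage_sample_gives_zero_column(self, toy):
        cov = toy.coverage()
        zero = {"seq": CoverageVector.zeros("seq", 16)}
        regions = find_expressed_regions(cov["seq"], 2, 1)
        mat = region_coverage_matrix(regions, {"toy": cov, "blank": zero})
        blank_col = mat.sample_ids.index("blank")
        assert (mat.values[:, blank_col] == 0).all()

    def test_scale_with_target_equal_auc_is_identity(self, toy):
        cov = toy.coverage()
        regions = find_expressed_regions(cov["seq"], 2, 1)
        raw = region_coverage_matrix(regions, {"toy": cov})
        scaled = region_coverage_matrix(
            regions, {"toy": cov}, scale=True, aucs={"toy": 45}, target=45
        )
        np.testing.assert_allclose(scaled.values, raw.values)
        assert scaled.scaled

    def test_missing_contig_names_sample(self, toy):
        cov = toy.coverage()
        regions = [GenomicInterval("chr9", 1, 5)]
        with pytest.raises(ValueError, match="toy.*chr9"):
            region_coverage_matrix(regions, {"toy": cov})


class TestAnnotateRegions:
    def test_toy_classification(self, toy):
        regions = [
            GenomicInterval("seq", 1, 5),    # inside exon [1,5]
            GenomicInterval("seq", 10, 11),  # in gene span but not exonic
        ]
        annos = annotate_regions(regions, toy.model)
        assert (annos[0].exonic, annos[0].intronic, annos[0].intergenic) == (5, 0, 0)
        assert (annos[1].exonic, annos[1].intronic, annos[1].intergenic) == (0, 2, 0)

    def test_gene_free_contig_is_all_intergenic(self, toy):
        (a,) = annotate_regions([GenomicInterval("chrEmpty", 5, 14)], toy.model)
        assert (a.exonic, a.intronic, a.intergenic) == (0, 0, 10)

    def test_classes_partition_region_width(self, toy):
        rng = np.random.default_rng(3)
        regions = [
            GenomicInterval("seq", s := int(rng.integers(1, 15)),
                            int(rng.integers(s, 17)))
            for _ in range(50)
        ]
        for a in annotate_regions(regions, toy.model):
            assert a.exonic + a.intronic + a.intergenic == a.width
            assert min(a.exonic, a.intronic, a.intergenic) >= 0


class TestRegionBaseCoverage:
    def test_pad_2_slice(self, toy):
        cov = toy.coverage()
        (entry,) = region_base_coverage(
            [GenomicInterval("seq", 8, 8)], {"toy": cov}, pad=2
        )
        assert (entry["padded"].start, entry["padded"].end) == (6, 10)
        assert entry["samples"]["toy"].tolist() == [2, 2, 3, 1, 3]

    def test_pad_0_is_exact_slice(self, toy):
        cov = toy.coverage()
        (entry,) = region_base_coverage(
            [GenomicInterval("seq", 13, 14)], {"toy": cov}, pad=0
        )
        assert entry["samples"]["toy"].tolist() == [4, 4]

    def test_padded_width_without_clipping(self, toy):
        cov = toy.coverage()
        (entry,) = region_base_coverage(
            [GenomicInterval("seq", 5, 8)], {"toy": cov}, pad=3
        )
        assert entry["padded"].width == 4 + 2 * 3

    def test_padding_clips_at_contig_bounds(self, toy):
        cov = toy.coverage()
        (entry,) = region_base_coverage(
            [GenomicInterval("seq", 1, 2)], {"toy": cov}, pad=5
        )
        assert (entry["padded"].start, entry["padded"].end) == (1, 7)

    def test_track_scaling_multiplies_values(self, toy):
        cov = toy.coverage()
        (entry,) = region_base_coverage(
            [GenomicInterval("seq", 8, 8)], {"toy": cov}, pad=1,
            aucs={"toy": 45}, target_auc=90,
        )
        assert entry["samples"]["toy"].tolist() == [4.0, 6.0, 2.0]
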