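"""Coverage-count matrices, junction extraction and low-expression filtering."""

import numpy as np
import pytest

from covquant import (
    AlignedSegment,
    CountMatrix,
    GenomicInterval,
    SimConfig,
    count_gene,
    coverage_from_alignments,
    disjoint_exon_counts,
    extract_junctions,
    feature_coverage_count,
    filter_low_expression,
    gene_counts,
    recompose_exon_counts,
    simulate_experiment,
)


def iv(s, e, contig="seq"):
    return GenomicInterval(contig, s, e)


class TestFeatureCoverageCount:
    def test_toy_disjoint_exon_counts(self, toy_cov):
        """2+2+3 = 7 over bases 6-8; 19 over bases 1-5; 10 over 13-15."""
        assert feature_coverage_count(toy_cov, iv(6, 8)) == 7
        assert feature_coverage_count(toy_cov, iv(1, 5)) == 19
        assert feature_coverage_count(toy_cov, iv(13, 15)) == 10

    def test_zero_coverage_gives_zero(self):
        from covquant import CoverageVector

        assert feature_coverage_count(CoverageVector.zeros("c", 50), iv(5, 20, "c")) == 0

    def test_absent_contig_errors(self, toy_cov):
        with pytest.raises(ValueError, match="chrZ"):
            feature_coverage_count({"seq": toy_cov}, iv(1, 5, "chrZ"))


class TestGeneCounts:
    def test_toy_gene_count_is_36(self, toy, toy_cov):
        assert count_gene(toy_cov, "gene1", toy.model) == 36

    def test_unknown_gene_errors(self, toy, toy_cov):
        with pytest.raises(KeyError, match="nope"):
            count_gene(toy_cov, "nope", toy.model)

    def test_gene_count_equals_sum_of_disjoint_exons(self, toy):
        covs = {"toy": toy.coverage()}
        dj = disjoint_exon_counts(covs, toy.model)
        gm = gene_counts(covs, toy.model)
        assert dj.values.sum() == gm.values.sum() == 36

    def test_shared_bases_counted_once_within_gene(self, toy):
        """Exons [1,5] and [1,8] overlap, yet the gene count uses each
        exonic base once: 19 + 7 + 10, not 26 + 7 + 10."""
        cov = toy.coverage()["seq"]
        direct_exon_sums = sum(
            feature_coverage_count(cov, e) for e in toy.model.gene_exons["gene1"]
        )
        assert direct_exon_sums == 19 + 26 + 10  # double-counts bases 1-5
        assert count_gene(cov, "gene1", toy.model) == 36

    def test_simulated_gene_counts_match_dense_oracle(self):
        res = simulate_experiment(SimConfig(seed=21, n_samples=1,
                                            genes_per_contig=5))
        covs = {
            s: coverage_from_alignments(segs, res.contig_lengths)
            for s, segs in res.segments.items()
        }
        gm = gene_counts(covs, res.model)
        dense = {c: v.to_dense() for c, v in covs["sample1"].items()}
        from covquant import merge_intervals

        for fid, row in zip(gm.feature_ids, gm.values[:, 0]):
            union = merge_intervals(res.model.gene_exons[fid])
            expected = sum(
                dense[u.contig][u.start - 1 : u.end].sum() for u in union
            )
            assert row == expected


class TestRecomposeExonCounts:
    def test_toy_exon_1_8_recomposes_to_26(self, toy):
        covs = {"toy": toy.coverage()}
        dj = disjoint_exon_counts(covs, toy.model)
        exon = recompose_exon_counts(dj, toy.model)
        by_iv = {
            (iv_.start, iv_.end): v
            for iv_, v in zip(exon.intervals, exon.values[:, 0])
        }
        assert by_iv[(1, 8)] == 19 + 7
        assert by_iv[(1, 5)] == 19
        assert by_iv[(13, 15)] == 10

    def test_recomposed_equals_direct_count_per_exon(self):
        """Summing member disjoint exons == summing coverage over the exon."""
        res = simulate_experiment(SimConfig(seed=33, n_samples=2,
                                            genes_per_contig=6))
        covs = {
            s: coverage_from_alignments(segs, res.contig_lengths)
            for s, segs in res.segments.items()
        }
        dj = disjoint_exon_counts(covs, res.model)
        exon = recompose_exon_counts(dj, res.model)
        for fid, iv_, row in zip(exon.feature_ids, exon.intervals, exon.values):
            for s_idx, sample in enumerate(exon.sample_ids):
                direct = feature_coverage_count(covs[sample], iv_)
                assert row[s_idx] == direct

    def test_wrong_kind_rejected(self, toy):
        gm = gene_counts({"toy": toy.coverage()}, toy.model)
        with pytest.raises(ValueError, match="disjoint_exon"):
            recompose_exon_counts(gm, toy.model)


class TestExtractJunctions:
    def test_annotated_junction_from_toy_intron(self, toy):
        seg = AlignedSegment("r", "seq", (iv(4, 5), iv(13, 14)))
        records = extract_junctions({"s1": [seg]}, toy.model)
        assert len(records) == 1
        j = records[0]
        assert (j.interval.start, j.interval.end) == (6, 12)
        assert j.annotated
        assert j.counts == {"s1": 1}
        assert (j.donor, j.acceptor) == (5, 13)

    def test_unannotated_junction(self, toy):
        seg = AlignedSegment("r", "seq", (iv(4, 5), iv(11, 12)))
        (j,) = extract_junctions({"s1": [seg]}, toy.model)
        assert (j.interval.start, j.interval.end) == (6, 10)
        assert not j.annotated

    def test_unspliced_segments_give_empty_list(self, toy):
        segs = [AlignedSegment("r", "seq", (iv(1, 3),))]
        assert extract_junctions({"s1": segs}, toy.model) == []

    def test_toy_fixture_junction_census(self, toy):
        """Four spliced reads: three over annotated introns, one novel."""
        records = extract_junctions({"toy": toy.segments}, toy.model)
        table = {
            (j.interval.start, j.interval.end): (j.total(), j.annotated)
            for j in records
        }
        assert table == {(6, 12): (1, True), (9, 12): (2, True), (9, 9): (1, False)}

    def test_counts_accumulate_per_sample(self, toy):
        seg = AlignedSegment("r", "seq", (iv(4, 5), iv(13, 14)))
        (j,) = extract_junctions({"a": [seg, seg], "b": [seg]}, toy.model)
        assert j.counts == {"a": 2, "b": 1}


class TestFilterLowExpression:
    def test_strict_inequality_at_threshold(self):
        m = CountMatrix(
            ["f1", "f2", "f3"],
            [iv(1, 1, "c"), iv(2, 2, "c"), iv(3, 3, "c")],
            ["s1", "s2"],
            np.array([[0, 1], [1, 0], [1, 1]]) * np.array([[0.8], [1.0], [1.2]]),
            kind="gene",
            scaled=True,
        )
        # row means: 0.4, 0.5, 1.2
        assert filter_low_expression(m, 0.5).tolist() == [False, False, True]

    def test_threshold_zero_keeps_all_positive_rows(self):
        m = CountMatrix(
            ["a", "b"], [iv(1, 1, "c"), iv(2, 2, "c")], ["s"],
            np.array([[3], [1]]), kind="gene",
        )
        assert filter_low_expression(m, 0.0).tolist() == [True, True]

    def test_mask_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.integers(0, 4, size=(40, 6))
        m = CountMatrix(
            [f"f{i}" for i in range(40)],
            [iv(i + 1, i + 1, "c") for i in range(40)],
            [f"s{j}" for j in range(6)],
            values,
            kind="gene",
        )
        mask = filter_low_expression(m, 0.5)
        for i in range(40):
            assert mask[i] == (sum(values[i]) / 6 > 0.5)


class TestCountMatrix:
    def test_raw_matrix_must_be_integer(self):
        with pytest.raises(ValueError, match="integer"):
            CountMatrix(["f"], [iv(1, 2, "c")], ["s"], np.array([[1.5]]),
                        kind="gene", scaled=False)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            CountMatrix(["f"], [iv(1, 2, "c")], ["s"], np.array([[-1]]),
                        kind="gene")
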