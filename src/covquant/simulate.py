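"""Deterministic fixtures and a seeded read simulator with known truth.

Two sources of test data:

* :func:`make_toy_fixture` — a 16-bp contig, one gene with two isoforms
  (exons [1,5]+[13,15] and [1,8]+[13,15]) and 16 reads of length 3 whose
  20 aligned blocks give the per-base coverage
  (3,3,5,4,4,2,2,3,1,3,3,1,4,4,2,1), AUC 45, disjoint-exon counts
  (19, 7, 10) and gene count 36.  Every number in the package's worked
  examples traces back to this fixture.

* :func:`simulate_experiment` — a seeded generator of annotation + reads
  whose ground truth (per-gene exonic-base contributions, per-junction
  support, per-sample AUC) is recorded at generation time, so
  quantification can be checked for exact recovery.

The simulator emulates spliced alignment output: reads are placed in
transcript coordinates and split across introns when they cross exon
boundaries.  It does not model sequencing errors, GC or positional bias,
or fragment-size effects, so exact-recovery tests demonstrate algorithmic
correctness, not robustness to real-library noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .coverage import AlignedSegment, CoverageVector, coverage_from_alignments
from .genome import GeneModel, GenomicInterval, GtfRecord, build_gene_model, merge_intervals
from .scaling import SampleInfo

__all__ = ["ToyFixture", "make_toy_fixture", "SimConfig", "SimResult", "simulate_experiment"]

TOY_CONTIG = "seq"
TOY_CONTIG_LENGTH = 16

#: Per-base coverage of the toy fixture over bases 1..16.
TOY_COVERAGE = (3, 3, 5, 4, 4, 2, 2, 3, 1, 3, 3, 1, 4, 4, 2, 1)


@dataclass
class ToyFixture:
    """The worked micro-example: gene model, aligned reads, library stats."""

    model: GeneModel
    segments: list[AlignedSegment]
    sample_info: SampleInfo
    contig_lengths: dict[str, int]

    def coverage(self) -> dict[str, CoverageVector]:
        return coverage_from_alignments(self.segments, self.contig_lengths)


def _seg(read_id: str, blocks: list[tuple[int, int]], clipped: int = 0) -> AlignedSegment:
    return AlignedSegment(
        read_id,
        TOY_CONTIG,
        tuple(GenomicInterval(TOY_CONTIG, s, e) for s, e in blocks),
        clipped,
    )


def make_toy_fixture() -> ToyFixture:
    """Build the 16-read toy example with its 20 aligned blocks.

    The printed block list fixes only the (start, width) multiset; the
    grouping into reads is reconstructed so that every invariant holds:
    16 reads of length 3, ten unspliced full-length reads, four spliced
    reads (three across annotated introns [6,12] / [9,12], one across the
    unannotated gap [9,9]), and two soft-clipped reads ([1,1] with 2
    clipped bases, [3,4] with 1), for 48 read bases, 3 clipped, AUC 45.
    """
    records = [
        GtfRecord(TOY_CONTIG, "exon", 1, 5, ".", {"gene_id": "gene1", "transcript_id": "tx1"}, 1),
        GtfRecord(TOY_CONTIG, "exon", 13, 15, ".", {"gene_id": "gene1", "transcript_id": "tx1"}, 2),
        GtfRecord(TOY_CONTIG, "exon", 1, 8, ".", {"gene_id": "gene1", "transcript_id": "tx2"}, 3),
        GtfRecord(TOY_CONTIG, "exon", 13, 15, ".", {"gene_id": "gene1", "transcript_id": "tx2"}, 4),
    ]
    model = build_gene_model(records)

    segments = [
        # ten full-length unspliced reads
        _seg("read01", [(1, 3)]),
        _seg("read02", [(1, 3)]),
        _seg("read03", [(2, 4)]),
        _seg("read04", [(3, 5)]),
        _seg("read05", [(4, 6)]),
        _seg("read06", [(5, 7)]),
        _seg("read07", [(9, 11)]),
        _seg("read08", [(10, 12)]),
        _seg("read09", [(13, 15)]),
        _seg("read10", [(14, 16)]),
        # four spliced reads (block pairs total 3 aligned bases)
        _seg("read11", [(5, 5), (13, 14)]),   # skips [6,12]  (tx1 intron)
        _seg("read12", [(7, 8), (13, 13)]),   # skips [9,12]  (tx2 intron)
        _seg("read13", [(8, 8), (13, 14)]),   # skips [9,12]  (tx2 intron)
        _seg("read14", [(8, 8), (10, 11)]),   # skips [9,9]   (unannotated)
        # two soft-clipped reads
        _seg("read15", [(1, 1)], clipped=2),
        _seg("read16", [(3, 4)], clipped=1),
    ]
    info = SampleInfo(
        sample_id="toy",
        mapped_read_count=16,
        avg_read_length=3,
        auc=45,
        paired_end=False,
    )
    return ToyFixture(model, segments, info, {TOY_CONTIG: TOY_CONTIG_LENGTH})


# --------------------------------------------------------------------------
# Seeded simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults describe a small bulk RNA-seq-like setting that runs in well
    under a second: one 100-kb-scale contig region per 8 genes, 100-bp
    single-end reads, moderate per-gene depth, a fifth of reads spliced.
    """

    seed: int = 0
    n_samples: int = 2
    n_contigs: int = 1
    genes_per_contig: int = 8
    read_length: int = 100
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_width: tuple[int, int] = (150, 400)
    intron_width: tuple[int, int] = (100, 1000)
    intergenic_gap: tuple[int, int] = (500, 3000)
    transcripts_per_gene: tuple[int, int] = (1, 3)
    reads_per_gene: tuple[int, int] = (50, 150)
    spliced_fraction: float = 0.2
    clip_fraction: float = 0.0
    clip_length: int = 5
    intergenic_read_fraction: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.spliced_fraction, self.clip_fraction, self.intergenic_read_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.read_length < 1 or self.clip_length < 0:
            raise ValueError("read_length must be >= 1 and clip_length >= 0")
        if self.clip_length >= self.read_length and self.clip_fraction > 0:
            raise ValueError("clip_length must be smaller than read_length")


@dataclass
class SimResult:
    """Simulated annotation, per-sample reads, and ground truth."""

    config: SimConfig
    model: GeneModel
    contig_lengths: dict[str, int]
    segments: dict[str, list[AlignedSegment]]
    sample_infos: dict[str, SampleInfo]
    gene_truth: pd.DataFrame           # gene_id x sample: exonic-base contributions
    junction_truth: dict[str, dict[tuple[str, int, int], int]]  # sample -> junction -> support
    reads_per_gene_truth: pd.DataFrame  # gene_id x sample: reads drawn from the gene

    def write(self, outdir: str | Path) -> None:
        """Emit GTF, one SAM per sample, sample-info TSV and truth TSVs."""
        from . import io as cio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_gtf(self.model, outdir / "annotation.gtf")
        for sample in sorted(self.segments):
            cio.write_sam(
                self.segments[sample], self.contig_lengths, outdir / f"{sample}.sam"
            )
        cio.write_sample_info(
            [self.sample_infos[s] for s in sorted(self.sample_infos)],
            outdir / "sample_info.tsv",
            meta={"seed": self.config.seed},
        )
        self.gene_truth.to_csv(outdir / "truth_gene_counts.tsv", sep="\t")
        self.reads_per_gene_truth.to_csv(outdir / "truth_reads_per_gene.tsv", sep="\t")
        rows = []
        for sample in sorted(self.junction_truth):
            for (contig, start, end), n in sorted(self.junction_truth[sample].items()):
                rows.append((sample, contig, start, end, n))
        pd.DataFrame(
            rows, columns=["sample", "contig", "start", "end", "support"]
        ).to_csv(outdir / "truth_junctions.tsv", sep="\t", index=False)


def _make_annotation(cfg: SimConfig, rng: np.random.Generator):
    """Lay out non-overlapping genes along each contig; return model parts."""
    records: list[GtfRecord] = []
    contig_lengths: dict[str, int] = {}
    line = 0
    for c in range(cfg.n_contigs):
        contig = f"ctg{c + 1}"
        cursor = int(rng.integers(*cfg.intergenic_gap)) + 1
        for g in range(cfg.genes_per_contig):
            gene_id = f"g{c + 1}_{g + 1:03d}"
            n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            exons: list[GenomicInterval] = []
            pos = cursor
            for _ in range(n_exons):
                width = int(rng.integers(cfg.exon_width[0], cfg.exon_width[1] + 1))
                exons.append(GenomicInterval(contig, pos, pos + width - 1))
                pos += width + int(rng.integers(cfg.intron_width[0], cfg.intron_width[1] + 1))
            n_tx = int(
                rng.integers(cfg.transcripts_per_gene[0], cfg.transcripts_per_gene[1] + 1)
            )
            tx_exon_sets: list[list[GenomicInterval]] = [list(exons)]
            for t in range(1, n_tx):
                keep = sorted(
                    rng.choice(n_exons, size=int(rng.integers(1, n_exons + 1)), replace=False)
                )
                tx_exons = [exons[i] for i in keep]
                # alternative 3' exon ends exercise the disjoin nontrivially
                if len(tx_exons) >= 1 and rng.random() < 0.5:
                    i = int(rng.integers(len(tx_exons)))
                    ext = int(rng.integers(10, 60))
                    e = tx_exons[i]
                    tx_exons[i] = GenomicInterval(contig, e.start, e.end + ext)
                tx_exon_sets.append(tx_exons)
            for t, tx_exons in enumerate(tx_exon_sets):
                tx_id = f"{gene_id}.t{t + 1}"
                for e in tx_exons:
                    line += 1
                    records.append(
                        GtfRecord(
                            contig, "exon", e.start, e.end, "+",
                            {"gene_id": gene_id, "transcript_id": tx_id}, line,
                        )
                    )
            cursor = max(e.end for s in tx_exon_sets for e in s) + int(
                rng.integers(*cfg.intergenic_gap)
            ) + 1
        contig_lengths[contig] = cursor + int(rng.integers(*cfg.intergenic_gap))
    return records, contig_lengths


def _blocks_in_transcript(
    tx_exons: list[GenomicInterval], tstart: int, length: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate placement to genomic blocks (splicing)."""
    blocks: list[tuple[int, int]] = []
    offset = 0  # transcript bases before current exon
    remaining_start, remaining = tstart, length
    for exon in tx_exons:
        w = exon.width
        lo = max(remaining_start, offset + 1)
        hi = min(remaining_start + remaining - 1, offset + w)
        if lo <= hi:
            blocks.append((exon.start + lo - offset - 1, exon.start + hi - offset - 1))
        offset += w
    return blocks


def simulate_experiment(cfg: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate annotation + reads with recorded ground truth.

    Reads are drawn per gene from a uniform depth range, placed uniformly
    in transcript coordinates: a *spliced* read is forced to cross a
    randomly chosen exon-exon boundary of its transcript, an unspliced
    read to sit inside a single exon.  Soft clipping trims the leading
    ``clip_length`` bases of an unspliced read's block; intergenic reads
    fall in gaps between genes.  Per-sample random streams derive from
    (seed, sample index), so adding samples never perturbs earlier ones.

    Raises
    ------
    ValueError
        If the configuration is infeasible (read length exceeding every
        usable placement of some transcript).
    """
    anno_rng = np.random.default_rng([cfg.seed, 0])
    records, contig_lengths = _make_annotation(cfg, anno_rng)
    model = build_gene_model(records)

    for tx_id, exons in model.transcripts.items():
        if sum(e.width for e in exons) < cfg.read_length:
            raise ValueError(
                f"infeasible config: read length {cfg.read_length} exceeds "
                f"transcript {tx_id!r} length {sum(e.width for e in exons)}"
            )

    gene_ids = sorted(model.genes)
    exonic_union_by_gene = {
        g: merge_intervals(model.gene_exons[g]) for g in gene_ids
    }
    # intergenic gaps (outside every gene span) wide enough to hold a read
    spans_by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(model.gene_span(g) for g in gene_ids):
        spans_by_contig.setdefault(iv.contig, []).append(iv)
    gaps: list[GenomicInterval] = []
    for contig, length in contig_lengths.items():
        spans = spans_by_contig.get(contig, [])
        prev_end = 0
        for iv in spans + [GenomicInterval(contig, length + 1, length + 1)]:
            if iv.start - prev_end - 1 >= cfg.read_length + 2:
                gaps.append(GenomicInterval(contig, prev_end + 1, iv.start - 1))
            prev_end = max(prev_end, iv.end)

    samples = [f"sample{i + 1}" for i in range(cfg.n_samples)]
    segments: dict[str, list[AlignedSegment]] = {}
    infos: dict[str, SampleInfo] = {}
    gene_truth = pd.DataFrame(0.0, index=gene_ids, columns=samples)
    reads_truth = pd.DataFrame(0, index=gene_ids, columns=samples)
    junction_truth: dict[str, dict[tuple[str, int, int], int]] = {}

    for s_idx, sample in enumerate(samples):
        rng = np.random.default_rng([cfg.seed, s_idx + 1])
        segs: list[AlignedSegment] = []
        jx: dict[tuple[str, int, int], int] = {}
        aligned_bases = 0
        read_no = 0
        for gene_id in gene_ids:
            tx_ids = sorted(model.genes[gene_id])
            n_reads = int(rng.integers(cfg.reads_per_gene[0], cfg.reads_per_gene[1] + 1))
            reads_truth.loc[gene_id, sample] = n_reads
            for _ in range(n_reads):
                tx_exons = model.transcripts[tx_ids[int(rng.integers(len(tx_ids)))]]
                tx_len = sum(e.width for e in tx_exons)
                spliced = (
                    len(tx_exons) >= 2
                    and rng.random() < cfg.spliced_fraction
                )
                if spliced:
                    # cross the boundary after exon j: transcript positions
                    # spanning cumulative[j]
                    j = int(rng.integers(len(tx_exons) - 1))
                    boundary = sum(e.width for e in tx_exons[: j + 1])
                    lo = max(1, boundary - cfg.read_length + 2)
                    hi = min(boundary, tx_len - cfg.read_length + 1)
                    if lo > hi:
                        spliced = False
                    else:
                        tstart = int(rng.integers(lo, hi + 1))
                if not spliced:
                    # fit inside one exon
                    fit = [e for e in tx_exons if e.width >= cfg.read_length]
                    if not fit:
                        raise ValueError(
                            "infeasible config: no exon can hold an unspliced "
                            f"read of length {cfg.read_length} in gene {gene_id!r}"
                        )
                    exon = fit[int(rng.integers(len(fit)))]
                    offset = 0
                    for e in tx_exons:
                        if e is exon:
                            break
                        offset += e.width
                    tstart = offset + 1 + int(rng.integers(exon.width - cfg.read_length + 1))
                blocks = _blocks_in_transcript(tx_exons, tstart, cfg.read_length)
                clipped = 0
                if not spliced and cfg.clip_fraction > 0 and rng.random() < cfg.clip_fraction:
                    clipped = cfg.clip_length
                    (bs, be) = blocks[0]
                    blocks = [(bs + clipped, be)]
                read_no += 1
                contig = tx_exons[0].contig
                seg = AlignedSegment(
                    f"{sample}_r{read_no:06d}",
                    contig,
                    tuple(GenomicInterval(contig, a, b) for a, b in blocks),
                    clipped,
                )
                segs.append(seg)
                aligned_bases += seg.aligned_bases
                for gap in seg.junctions():
                    key = (gap.contig, gap.start, gap.end)
                    jx[key] = jx.get(key, 0) + 1
                for gid in gene_ids:
                    pieces = exonic_union_by_gene[gid]
                    if pieces[0].contig != contig:
                        continue
                    contrib = sum(
                        b.overlap_width(p) for b in seg.blocks for p in pieces
                    )
                    if contrib:
                        gene_truth.loc[gid, sample] += contrib
        n_intergenic = int(round(cfg.intergenic_read_fraction * read_no))
        for _ in range(n_intergenic):
            if not gaps:
                break
            gap = gaps[int(rng.integers(len(gaps)))]
            start = gap.start + int(rng.integers(gap.width - cfg.read_length + 1))
            read_no += 1
            seg = AlignedSegment(
                f"{sample}_r{read_no:06d}",
                gap.contig,
                (GenomicInterval(gap.contig, start, start + cfg.read_length - 1),),
            )
            segs.append(seg)
            aligned_bases += cfg.read_length
        segments[sample] = segs
        junction_truth[sample] = jx
        infos[sample] = SampleInfo(
            sample_id=sample,
            mapped_read_count=read_no,
            avg_read_length=cfg.read_length,
            auc=aligned_bases,
            paired_end=False,
        )

    result = SimResult(
        config=cfg,
        model=model,
        contig_lengths=contig_lengths,
        segments=segments,
        sample_infos=infos,
        gene_truth=gene_truth,
        junction_truth=junction_truth,
        reads_per_gene_truth=reads_truth,
    )
    if outdir is not None:
        result.write(outdir)
    return result
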