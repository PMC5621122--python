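"""Format adapters: SAM, GTF/GFF2, BED6/BED12, bedGraph, TSV tables.

Internal coordinates are 1-based closed; BED and bedGraph are written and
read as 0-based half-open, SAM as 1-based.  bedGraph (plain text) is the
canonical coverage interchange format here; zero-coverage runs are omitted
on write and restored on read, so write -> read is the identity on
:class:`~covquant.coverage.CoverageVector`.

Output tables carry ``#`` header comment lines (tool version, seed, config
hash) that readers skip.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .coverage import AlignedSegment, CoverageVector, blocks_from_cigar
from .genome import GeneModel, GenomicInterval, GtfRecord
from .quantify import CountMatrix, JunctionRecord
from .regions import ExpressedRegion
from .scaling import SampleInfo

__all__ = [
    "read_gtf",
    "write_gtf",
    "read_sam",
    "write_sam",
    "read_bed12",
    "write_bedgraph",
    "read_bedgraph",
    "write_disjoint_exons_bed",
    "write_regions_bed",
    "read_regions_bed",
    "read_genome_file",
    "write_count_matrix",
    "read_count_matrix",
    "write_junctions",
    "read_sample_info",
    "write_sample_info",
]

logger = logging.getLogger("covquant")

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GTF_ATTR_BARE = re.compile(r"(\w+)\s*=?\s*([^;\s\"]+)")


class InputFormatError(ValueError):
    """Raised when an input file violates its format contract (exit code 3)."""


def _header_lines(meta: Mapping[str, object] | None) -> list[str]:
    lines = [f"#covquant={__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"#{key}={value}")
    return lines


# --------------------------------------------------------------------------
# GTF / GFF2
# --------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[GtfRecord]:
    """Parse GTF/GFF2 records; attributes read as ``key "value"`` pairs."""
    records: list[GtfRecord] = []
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise InputFormatError(
                    f"{path}: line {line_number}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            contig, _source, feature, start, end, _score, strand, _frame, attrs = (
                fields[:9]
            )
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise InputFormatError(
                    f"{path}: line {line_number}: non-integer coordinates"
                ) from None
            attributes = dict(_GTF_ATTR.findall(attrs))
            if not attributes:
                attributes = dict(_GTF_ATTR_BARE.findall(attrs))
            records.append(
                GtfRecord(
                    contig=contig,
                    feature=feature,
                    start=start_i,
                    end=end_i,
                    strand=strand if strand in "+-" else ".",
                    attributes=attributes,
                    line_number=line_number,
                )
            )
    return records


def write_gtf(model: GeneModel, path: str | Path) -> None:
    """Write the model's exons as GTF exon records (one line per exon use)."""
    with open(path, "w") as fh:
        for gene_id in sorted(model.genes):
            for tx_id in sorted(model.genes[gene_id]):
                for exon in model.transcripts[tx_id]:
                    attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
                    fh.write(
                        f"{exon.contig}\tcovquant\texon\t{exon.start}\t{exon.end}"
                        f"\t.\t{exon.strand}\t.\t{attrs}\n"
                    )


# --------------------------------------------------------------------------
# SAM
# --------------------------------------------------------------------------

def read_sam(
    path: str | Path,
    include_secondary: bool = False,
) -> tuple[list[AlignedSegment], dict[str, int]]:
    """Read a SAM file into aligned segments plus contig lengths.

    One segment per mapped primary record (secondary/supplementary skipped
    unless *include_secondary*); unmapped records are skipped with a
    counted warning.  Blocks, clipping and junction gaps come from the
    CIGAR string.

    Raises
    ------
    InputFormatError
        If the header lacks an @SQ line for a used contig.
    """
    segments: list[AlignedSegment] = []
    skipped_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        contig_lengths = {
            sam.get_reference_name(i): sam.get_reference_length(
                sam.get_reference_name(i)
            )
            for i in range(sam.nreferences)
        }
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                skipped_unmapped += 1
                continue
            if not include_secondary and (rec.is_secondary or rec.is_supplementary):
                continue
            contig = rec.reference_name
            if contig not in contig_lengths:
                raise InputFormatError(
                    f"{path}: contig {contig!r} used by read {rec.query_name!r} "
                    "has no @SQ header line"
                )
            try:
                blocks, clipped, _ = blocks_from_cigar(
                    rec.reference_start + 1, rec.cigarstring or "*"
                )
            except ValueError as exc:
                raise InputFormatError(
                    f"{path}: read {rec.query_name!r}: {exc}"
                ) from None
            segments.append(
                AlignedSegment(
                    rec.query_name,
                    contig,
                    tuple(GenomicInterval(contig, s, e) for s, e in blocks),
                    clipped,
                )
            )
    if skipped_unmapped:
        logger.warning("skipped %d unmapped records in %s", skipped_unmapped, path)
    return segments, contig_lengths


def write_sam(
    segments: Iterable[AlignedSegment],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write segments as a minimal text SAM (soft clip emitted leading)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig in sorted(contig_lengths):
            fh.write(f"@SQ\tSN:{contig}\tLN:{contig_lengths[contig]}\n")
        for seg in segments:
            parts = []
            if seg.clipped_bases:
                parts.append(f"{seg.clipped_bases}S")
            for i, b in enumerate(seg.blocks):
                if i:
                    gap = b.start - seg.blocks[i - 1].end - 1
                    parts.append(f"{gap}N")
                parts.append(f"{b.width}M")
            cigar = "".join(parts)
            fh.write(
                f"{seg.read_id}\t0\t{seg.contig}\t{seg.blocks[0].start}\t255\t"
                f"{cigar}\t*\t0\t0\t*\t*\n"
            )


def read_bed12(path: str | Path) -> list[AlignedSegment]:
    """Read BED12 lines as aligned segments (blockStarts/blockSizes)."""
    segments: list[AlignedSegment] = []
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise InputFormatError(
                    f"{path}: line {line_number}: BED12 needs 12 fields, got {len(f)}"
                )
            contig, chrom_start, name = f[0], int(f[1]), f[3]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise InputFormatError(
                    f"{path}: line {line_number}: blockCount disagrees with "
                    "blockSizes/blockStarts"
                )
            blocks = tuple(
                GenomicInterval(contig, chrom_start + s + 1, chrom_start + s + sz)
                for s, sz in zip(starts, sizes)
            )
            segments.append(AlignedSegment(name, contig, blocks))
    return segments


# --------------------------------------------------------------------------
# bedGraph
# --------------------------------------------------------------------------

def _fmt_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_bedgraph(
    coverage: CoverageVector | Mapping[str, CoverageVector],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write coverage as bedGraph (0-based half-open); zero runs omitted."""
    vectors = (
        {coverage.contig: coverage}
        if isinstance(coverage, CoverageVector)
        else coverage
    )
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        for contig in sorted(vectors):
            for start, end, value in vectors[contig].runs():
                if value != 0:
                    fh.write(f"{contig}\t{start - 1}\t{end}\t{_fmt_value(value)}\n")


def read_bedgraph(
    path: str | Path, contig_lengths: Mapping[str, int]
) -> dict[str, CoverageVector]:
    """Read bedGraph into per-contig coverage; gaps are zero coverage.

    Raises
    ------
    InputFormatError
        On overlapping or out-of-order-overlapping lines, unknown contigs,
        or intervals beyond the contig length.
    """
    dense = {
        contig: np.zeros(int(length)) for contig, length in contig_lengths.items()
    }
    seen_to: dict[str, int] = {}
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise InputFormatError(
                    f"{path}: line {line_number}: bedGraph needs 4 fields"
                )
            contig, start0, end0, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if contig not in dense:
                raise InputFormatError(
                    f"{path}: line {line_number}: unknown contig {contig!r}"
                )
            if end0 > contig_lengths[contig]:
                raise InputFormatError(
                    f"{path}: line {line_number}: interval ends at {end0}, beyond "
                    f"contig {contig!r} length {contig_lengths[contig]}"
                )
            if (dense[contig][start0:end0] != 0).any():
                raise InputFormatError(
                    f"{path}: line {line_number}: overlapping bedGraph intervals "
                    f"on {contig!r}"
                )
            dense[contig][start0:end0] = value
    out = {}
    for contig, arr in dense.items():
        if np.allclose(arr, np.round(arr)):
            arr = arr.astype(np.int64)
        out[contig] = CoverageVector.from_dense(contig, arr)
    return out


# --------------------------------------------------------------------------
# BED writers
# --------------------------------------------------------------------------

def write_disjoint_exons_bed(
    model: GeneModel, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    """BED6 of disjoint exons; name = ``gene_id:ordinal``."""
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        for gene_id in sorted(model.disjoint_exons):
            for ordinal, dj in enumerate(model.disjoint_exons[gene_id], start=1):
                fh.write(
                    f"{dj.contig}\t{dj.start - 1}\t{dj.end}\t{gene_id}:{ordinal}"
                    f"\t0\t{dj.strand}\n"
                )


def write_regions_bed(
    regions: Sequence[ExpressedRegion],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """BED6+ of expressed regions: value, area, cluster, cluster_length."""
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        for i, r in enumerate(regions, start=1):
            iv = r.interval
            fh.write(
                f"{iv.contig}\t{iv.start - 1}\t{iv.end}\tregion{i}\t0\t{iv.strand}"
                f"\t{r.value!r}\t{r.area!r}\t{r.cluster}\t{r.cluster_length}\n"
            )


# --------------------------------------------------------------------------
# TSV tables
# --------------------------------------------------------------------------

def write_count_matrix(
    matrix: CountMatrix, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    """Count matrix as TSV: feature_id, contig, start, end, one column per sample."""
    header = dict(meta or {})
    header.setdefault("kind", matrix.kind)
    header.setdefault("scaled", matrix.scaled)
    with open(path, "w") as fh:
        for line in _header_lines(header):
            fh.write(line + "\n")
        matrix.to_dataframe().to_csv(fh, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV written by :func:`write_count_matrix`."""
    kind, scaled = "gene", False
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].rstrip("\n").partition("=")
            if key == "kind":
                kind = value
            elif key == "scaled":
                scaled = value == "True"
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"feature_id", "contig", "start", "end"}
    if not required.issubset(df.columns):
        raise InputFormatError(
            f"{path}: count matrix needs columns {sorted(required)}"
        )
    sample_cols = [c for c in df.columns if c not in required]
    intervals = [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df["contig"], df["start"], df["end"])
    ]
    return CountMatrix(
        [str(x) for x in df["feature_id"]],
        intervals,
        sample_cols,
        df[sample_cols].to_numpy(),
        kind=kind,
        scaled=scaled,
    )


def write_junctions(
    junctions: Sequence[JunctionRecord],
    sample_ids: Sequence[str],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Junction table: skipped-interval BED-like coordinates + per-sample counts."""
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        cols = ["contig", "start", "end", "strand", "annotated", *sample_ids]
        fh.write("\t".join(cols) + "\n")
        for j in junctions:
            iv = j.interval
            row = [
                iv.contig,
                str(iv.start - 1),
                str(iv.end),
                iv.strand,
                "1" if j.annotated else "0",
            ] + [str(j.counts.get(s, 0)) for s in sample_ids]
            fh.write("\t".join(row) + "\n")


def read_regions_bed(path: str | Path) -> list[ExpressedRegion]:
    """Read a regions BED6+ (extra columns value, area, cluster, cluster_length)."""
    regions: list[ExpressedRegion] = []
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise InputFormatError(
                    f"{path}: line {line_number}: BED needs at least 3 fields"
                )
            iv = GenomicInterval(
                f[0], int(f[1]) + 1, int(f[2]), f[5] if len(f) > 5 and f[5] in "+-" else "."
            )
            value = float(f[6]) if len(f) > 6 else 0.0
            area = float(f[7]) if len(f) > 7 else 0.0
            cluster = int(f[8]) if len(f) > 8 else 0
            cluster_length = int(f[9]) if len(f) > 9 else 0
            regions.append(ExpressedRegion(iv, value, area, cluster, cluster_length))
    return regions


def read_genome_file(path: str | Path) -> dict[str, int]:
    """Two-column TSV of contig name and length (a samtools-style .genome file)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise InputFormatError(
                    f"{path}: line {line_number}: genome file needs contig<TAB>length"
                )
            lengths[f[0]] = int(f[1])
    return lengths


_SAMPLE_COLUMNS = ["sample_id", "mapped_read_count", "avg_read_length", "auc", "paired_end"]


def write_sample_info(
    samples: Iterable[SampleInfo], path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("\t".join(_SAMPLE_COLUMNS) + "\n")
        for s in samples:
            fh.write(
                f"{s.sample_id}\t{s.mapped_read_count}\t{_fmt_value(s.avg_read_length)}"
                f"\t{_fmt_value(s.auc)}\t{int(s.paired_end)}\n"
            )


def read_sample_info(path: str | Path) -> dict[str, SampleInfo]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: sample info lacks columns {sorted(missing)}")
    out: dict[str, SampleInfo] = {}
    for row in df.itertuples(index=False):
        info = SampleInfo(
            sample_id=str(row.sample_id),
            mapped_read_count=int(row.mapped_read_count),
            avg_read_length=float(row.avg_read_length),
            auc=float(row.auc),
            paired_end=bool(int(row.paired_end)),
        )
        out[info.sample_id] = info
    return out
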