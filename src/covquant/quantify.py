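"""Coverage-count matrices at disjoint-exon, exon, gene and junction level.

A *coverage count* is the sum of per-base read coverage over a feature's
bases — not a read count.  Counting is annotation-blind at the coverage
stage; the exonic mask is applied only when summing, so a base covered by
reads but outside every exon simply never enters a feature sum.

Gene counts sum each exonic base once (via disjoint exons); recomposed
exon counts deliberately double-count bases shared by overlapping exons,
matching how exon-level matrices are conventionally rebuilt from
disjoint-exon matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import AlignedSegment, CoverageVector
from .genome import GeneModel, GenomicInterval

__all__ = [
    "CountMatrix",
    "JunctionRecord",
    "feature_coverage_count",
    "count_gene",
    "disjoint_exon_counts",
    "gene_counts",
    "recompose_exon_counts",
    "extract_junctions",
    "filter_low_expression",
]

CoverageMap = Mapping[str, CoverageVector]


@dataclass
class CountMatrix:
    """Features x samples coverage counts with interval metadata.

    ``kind`` is one of {disjoint_exon, exon, gene, junction, region}.
    Raw (unscaled) matrices hold integers; scaled matrices hold reals.
    Feature order is (contig, start, end, id) lexicographic.
    """

    feature_ids: list[str]
    intervals: list[GenomicInterval]
    sample_ids: list[str]
    values: np.ndarray
    kind: str
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match features x samples")
        if len(self.intervals) != len(self.feature_ids):
            raise ValueError("one interval per feature required")
        if self.values.size and (self.values < 0).any():
            raise ValueError("count matrices are non-negative")
        if not self.scaled and self.values.size:
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("raw count matrices must be integer-valued")

    def to_dataframe(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "contig": [iv.contig for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
            }
        )
        counts = pd.DataFrame(self.values, columns=self.sample_ids)
        return pd.concat([meta, counts], axis=1)

    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def column_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)


def _sorted_feature_order(
    ids: Sequence[str], intervals: Sequence[GenomicInterval]
) -> list[int]:
    return sorted(
        range(len(ids)),
        key=lambda i: (intervals[i].contig, intervals[i].start, intervals[i].end, ids[i]),
    )


def feature_coverage_count(
    coverage: CoverageVector | CoverageMap, feature: GenomicInterval
) -> float:
    """Sum of per-base coverage over the feature's bases.

    Raises
    ------
    ValueError
        If the feature's contig is absent from the coverage (or does not
        match a single-contig vector), or the feature exceeds the contig.
    """
    if isinstance(coverage, CoverageVector):
        if coverage.contig != feature.contig:
            raise ValueError(
                f"feature on contig {feature.contig!r} but coverage is for "
                f"{coverage.contig!r}"
            )
        vec = coverage
    else:
        vec = coverage.get(feature.contig)
        if vec is None:
            raise ValueError(f"no coverage for contig {feature.contig!r}")
    return vec.region_sum(feature.start, feature.end)


def count_gene(
    coverage: CoverageVector | CoverageMap, gene_id: str, model: GeneModel
) -> float:
    """Gene coverage count: sum over the gene's disjoint exons.

    Bases shared by several exons of the gene are counted once.
    """
    if gene_id not in model.disjoint_exons:
        raise KeyError(f"unknown gene id {gene_id!r}")
    return sum(
        feature_coverage_count(coverage, dj) for dj in model.disjoint_exons[gene_id]
    )


def _counts_for_features(
    ids: list[str],
    intervals: list[GenomicInterval],
    coverages: Mapping[str, CoverageMap],
    kind: str,
) -> CountMatrix:
    order = _sorted_feature_order(ids, intervals)
    ids = [ids[i] for i in order]
    intervals = [intervals[i] for i in order]
    sample_ids = list(coverages)
    values = np.zeros((len(ids), len(sample_ids)), dtype=np.int64)
    for s, sample in enumerate(sample_ids):
        cov = coverages[sample]
        for f, iv in enumerate(intervals):
            values[f, s] = int(feature_coverage_count(cov, iv))
    return CountMatrix(ids, intervals, sample_ids, values, kind=kind)


def disjoint_exon_counts(
    coverages: Mapping[str, CoverageMap], model: GeneModel
) -> CountMatrix:
    """Disjoint-exon x sample coverage-count matrix.

    Feature ids are ``gene_id:ordinal`` with ordinals following the gene's
    disjoint exons in genomic order.
    """
    ids: list[str] = []
    intervals: list[GenomicInterval] = []
    for gene_id in sorted(model.disjoint_exons):
        for ordinal, dj in enumerate(model.disjoint_exons[gene_id], start=1):
            ids.append(f"{gene_id}:{ordinal}")
            intervals.append(dj)
    return _counts_for_features(ids, intervals, coverages, kind="disjoint_exon")


def gene_counts(
    coverages: Mapping[str, CoverageMap], model: GeneModel
) -> CountMatrix:
    """Gene x sample coverage-count matrix (each exonic base counted once)."""
    ids = sorted(model.genes)
    intervals = [model.gene_span(g) for g in ids]
    order = _sorted_feature_order(ids, intervals)
    ids = [ids[i] for i in order]
    intervals = [intervals[i] for i in order]
    sample_ids = list(coverages)
    values = np.zeros((len(ids), len(sample_ids)), dtype=np.int64)
    for s, sample in enumerate(sample_ids):
        for f, gene_id in enumerate(ids):
            values[f, s] = int(count_gene(coverages[sample], gene_id, model))
    return CountMatrix(ids, intervals, sample_ids, values, kind="gene")


def recompose_exon_counts(disjoint: CountMatrix, model: GeneModel) -> CountMatrix:
    """Rebuild original-exon counts by summing member disjoint-exon counts.

    Each exon's count is the sum over the disjoint exons it contains, so
    bases shared by overlapping exons are counted in each of them — the
    complement of the within-gene deduplication done for gene counts.

    Raises
    ------
    ValueError
        If the disjoint matrix lacks a feature required by the model
        (membership gap).
    """
    if disjoint.kind != "disjoint_exon":
        raise ValueError(f"expected a disjoint_exon matrix, got {disjoint.kind!r}")
    row_of = {fid: i for i, fid in enumerate(disjoint.feature_ids)}
    ids: list[str] = []
    intervals: list[GenomicInterval] = []
    values_rows: list[np.ndarray] = []
    for gene_id in sorted(model.gene_exons):
        exons = model.gene_exons[gene_id]
        sums = [np.zeros(len(disjoint.sample_ids), dtype=np.int64) for _ in exons]
        touched = [False] * len(exons)
        for ordinal, members in enumerate(model.membership[gene_id], start=1):
            fid = f"{gene_id}:{ordinal}"
            if fid not in row_of:
                raise ValueError(f"disjoint matrix lacks feature {fid!r}")
            row = disjoint.values[row_of[fid]]
            for exon_idx in members:
                sums[exon_idx] = sums[exon_idx] + row
                touched[exon_idx] = True
        for exon_idx, exon in enumerate(exons):
            if not touched[exon_idx] and exon.width > 0:
                raise ValueError(
                    f"membership gap: exon {exon_idx} of gene {gene_id!r} has "
                    "no member disjoint exon"
                )
            ids.append(f"{gene_id}:exon{exon_idx + 1}")
            intervals.append(exon)
            values_rows.append(sums[exon_idx])
    order = _sorted_feature_order(ids, intervals)
    return CountMatrix(
        [ids[i] for i in order],
        [intervals[i] for i in order],
        list(disjoint.sample_ids),
        np.vstack([values_rows[i] for i in order]),
        kind="exon",
        scaled=disjoint.scaled,
    )


@dataclass
class JunctionRecord:
    """A spliced-alignment junction: the skipped reference interval.

    ``interval`` spans the first to the last skipped base (the intron);
    the donor-side last exonic base is ``interval.start - 1`` and the
    acceptor-side first exonic base is ``interval.end + 1``.  ``annotated``
    is True when the skipped interval equals an intron implied by the
    consecutive exons of some annotated transcript.
    """

    interval: GenomicInterval
    counts: dict[str, int] = field(default_factory=dict)
    annotated: bool = False

    @property
    def donor(self) -> int:
        return self.interval.start - 1

    @property
    def acceptor(self) -> int:
        return self.interval.end + 1

    def total(self) -> int:
        return sum(self.counts.values())


def extract_junctions(
    segments_by_sample: Mapping[str, Iterable[AlignedSegment]],
    model: GeneModel | None = None,
) -> list[JunctionRecord]:
    """Collect exon-exon junctions from spliced alignments.

    Junction identity is the skipped (intron) interval per contig; the
    count for a sample is the number of its segments spanning that gap.
    With a :class:`GeneModel`, each junction is classified as annotated
    (matches an implied intron) or not.  Sorted by (contig, start, end).
    """
    records: dict[tuple[str, int, int], JunctionRecord] = {}
    for sample, segments in segments_by_sample.items():
        for seg in segments:
            for gap in seg.junctions():
                key = (gap.contig, gap.start, gap.end)
                rec = records.get(key)
                if rec is None:
                    rec = JunctionRecord(gap)
                    records[key] = rec
                rec.counts[sample] = rec.counts.get(sample, 0) + 1
    introns = model.implied_introns() if model is not None else set()
    out = [records[k] for k in sorted(records)]
    for rec in out:
        rec.annotated = (
            rec.interval.contig,
            rec.interval.start,
            rec.interval.end,
        ) in introns
    return out


def filter_low_expression(matrix: CountMatrix, threshold: float = 0.5) -> np.ndarray:
    """Boolean keep-mask for features whose mean count strictly exceeds
    *threshold* — the conventional low-expression filter before DE."""
    if not matrix.feature_ids:
        raise ValueError("cannot filter an empty matrix")
    return matrix.row_means() > threshold
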