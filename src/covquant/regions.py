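"""Annotation-agnostic expressed-region detection on coverage tracks.

An *expressed region* is a maximal run of bases whose coverage exceeds a
cutoff on a (typically mean) coverage track.  Regions carry the mean
coverage over their bases (``value``), the coverage sum (``area``), and a
cluster id grouping nearby regions (inter-region gap at most a maximum
gap).  Detection is purely data-driven — no gene annotation is consulted —
which makes the regions useful for finding intron retention, unannotated
exons and intergenic expression; a separate step classifies region bases
as exonic/intronic/intergenic against a gene model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coverage import CoverageVector
from .genome import GeneModel, GenomicInterval, merge_intervals
from .quantify import CountMatrix
from .scaling import scale_counts_auc

__all__ = [
    "ExpressedRegion",
    "RegionAnnotation",
    "find_expressed_regions",
    "filter_regions_by_width",
    "region_coverage_matrix",
    "annotate_regions",
    "region_base_coverage",
]

CoverageMap = Mapping[str, CoverageVector]


@dataclass
class ExpressedRegion:
    """A contiguous above-cutoff segment of a coverage track.

    ``value`` is the mean and ``area`` the sum of the *unthresholded*
    coverage over the region, so ``area == value * width`` to numeric
    tolerance.  ``index_start``/``index_end`` equal the genomic start/end
    (kept as separate fields for table compatibility).  ``cluster_length``
    is the genomic span of the region's cluster: end of its last region
    minus start of its first, plus one.
    """

    interval: GenomicInterval
    value: float
    area: float
    cluster: int = 0
    cluster_length: int = 0

    @property
    def index_start(self) -> int:
        return self.interval.start

    @property
    def index_end(self) -> int:
        return self.interval.end

    @property
    def width(self) -> int:
        return self.interval.width


def find_expressed_regions(
    coverage: CoverageVector,
    cutoff: float,
    max_cluster_gap: int = 3000,
    strict: bool = True,
) -> list[ExpressedRegion]:
    """Maximal runs of bases with coverage above *cutoff*, with clusters.

    Parameters
    ----------
    coverage
        The track to segment (raw, scaled or mean — value/area are taken
        from this track as given).
    cutoff
        Expression threshold; a base is expressed when its coverage is
        strictly greater than *cutoff* (set ``strict=False`` for >=).
    max_cluster_gap
        Consecutive regions whose gap is at most this many bases share a
        cluster id (1-based ids in genomic order).

    Returns regions sorted by start; empty list if nothing passes.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if max_cluster_gap < 0:
        raise ValueError("max_cluster_gap must be >= 0")

    regions: list[ExpressedRegion] = []
    run_start: int | None = None
    run_area = 0.0
    prev_end = 0
    for start, end, value in coverage.runs():
        expressed = value > cutoff if strict else value >= cutoff
        if expressed:
            if run_start is None:
                run_start = start
                run_area = 0.0
            run_area += value * (end - start + 1)
            prev_end = end
        elif run_start is not None:
            width = prev_end - run_start + 1
            regions.append(
                ExpressedRegion(
                    GenomicInterval(coverage.contig, run_start, prev_end),
                    value=run_area / width,
                    area=run_area,
                )
            )
            run_start = None
    if run_start is not None:
        width = prev_end - run_start + 1
        regions.append(
            ExpressedRegion(
                GenomicInterval(coverage.contig, run_start, prev_end),
                value=run_area / width,
                area=run_area,
            )
        )

    # cluster assignment: gap <= max_cluster_gap joins adjacent regions
    cluster_id = 0
    cluster_members: list[list[ExpressedRegion]] = []
    for region in regions:
        if (
            cluster_members
            and region.interval.start - cluster_members[-1][-1].interval.end - 1
            <= max_cluster_gap
        ):
            cluster_members[-1].append(region)
        else:
            cluster_members.append([region])
    for cluster_id, members in enumerate(cluster_members, start=1):
        span = members[-1].interval.end - members[0].interval.start + 1
        for region in members:
            region.cluster = cluster_id
            region.cluster_length = span
    return regions


def filter_regions_by_width(
    regions: Sequence[ExpressedRegion], min_width: int
) -> list[ExpressedRegion]:
    """Keep regions at least *min_width* bases long (inclusive)."""
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    return [r for r in regions if r.width >= min_width]


def region_coverage_matrix(
    regions: Sequence[ExpressedRegion | GenomicInterval],
    coverages: Mapping[str, CoverageMap],
    scale: bool = False,
    aucs: Mapping[str, float] | None = None,
    target: float = 40_000_000,
) -> CountMatrix:
    """Region x sample matrix of coverage sums over each region.

    Entry (r, s) is the coverage of sample *s* summed over region *r* —
    for the track the regions were called on, this equals the region's
    ``area``.  With ``scale=True`` each sample's column is rescaled to the
    target library size using that sample's AUC.

    Raises
    ------
    ValueError
        If a region's contig is missing from some sample's coverage
        (message names the sample and contig).
    """
    intervals = [
        r.interval if isinstance(r, ExpressedRegion) else r for r in regions
    ]
    ids = [f"{iv.contig}:{iv.start}-{iv.end}" for iv in intervals]
    sample_ids = list(coverages)
    values = np.zeros((len(intervals), len(sample_ids)), dtype=float)
    for s, sample in enumerate(sample_ids):
        cov = coverages[sample]
        for f, iv in enumerate(intervals):
            vec = cov.get(iv.contig)
            if vec is None:
                raise ValueError(
                    f"sample {sample!r} has no coverage for contig {iv.contig!r}"
                )
            values[f, s] = vec.region_sum(iv.start, iv.end)
    scaled = False
    if scale:
        if aucs is None:
            raise ValueError("scaling a region matrix requires per-sample AUCs")
        for s, sample in enumerate(sample_ids):
            values[:, s] = scale_counts_auc(values[:, s], aucs[sample], target)
        scaled = True
    if not scaled:
        values = values.astype(np.int64) if np.allclose(values, np.round(values)) else values
    return CountMatrix(ids, intervals, sample_ids, values, kind="region", scaled=scaled)


@dataclass
class RegionAnnotation:
    """Per-region base classification against a gene model.

    ``exonic + intronic + intergenic == width`` always: every base is in
    exactly one class (exonic wins over intronic where both apply).
    """

    region: GenomicInterval
    exonic: int
    intronic: int
    intergenic: int

    @property
    def width(self) -> int:
        return self.region.width


def _overlap_bases(region: GenomicInterval, pieces: Sequence[GenomicInterval]) -> int:
    return sum(region.overlap_width(p) for p in pieces)


def annotate_regions(
    regions: Sequence[ExpressedRegion | GenomicInterval], model: GeneModel
) -> list[RegionAnnotation]:
    """Classify every base of every region as exonic, intronic or intergenic.

    Exonic: inside the model's merged exonic union.  Intronic: inside some
    gene's span but not exonic.  Intergenic: neither.
    """
    if not model.genes:
        raise ValueError("gene model is empty")
    span_union: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(model.gene_span(g) for g in model.genes):
        span_union.setdefault(iv.contig, []).append(iv)
    out: list[RegionAnnotation] = []
    for r in regions:
        iv = r.interval if isinstance(r, ExpressedRegion) else r
        exonic = _overlap_bases(iv, model.exonic_union.get(iv.contig, []))
        genic = _overlap_bases(iv, span_union.get(iv.contig, []))
        out.append(
            RegionAnnotation(
                iv,
                exonic=exonic,
                intronic=genic - exonic,
                intergenic=iv.width - genic,
            )
        )
    return out


def region_base_coverage(
    regions: Sequence[ExpressedRegion | GenomicInterval],
    coverages: Mapping[str, CoverageMap],
    pad: int = 0,
    aucs: Mapping[str, float] | None = None,
    target_auc: float | None = None,
) -> list[dict]:
    """Base-level coverage per region per sample, with symmetric padding.

    Each region is widened by *pad* bases on both sides (clipped at contig
    bounds), and per-base coverage is extracted for every sample.  When
    *aucs* and *target_auc* are given, each sample's values are multiplied
    by ``target_auc / auc`` (track scaling).

    Returns one dict per region: ``{"region", "padded", "samples":
    {sample_id: np.ndarray over the padded interval}}``.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    out: list[dict] = []
    for r in regions:
        iv = r.interval if isinstance(r, ExpressedRegion) else r
        entry: dict = {"region": iv, "samples": {}}
        for sample, cov in coverages.items():
            vec = cov.get(iv.contig)
            if vec is None:
                raise ValueError(
                    f"sample {sample!r} has no coverage for contig {iv.contig!r}"
                )
            padded = iv.padded(pad, contig_length=vec.length)
            entry["padded"] = padded
            values = vec.slice(padded.start, padded.end).astype(float)
            if aucs is not None and target_auc is not None:
                values = values * (target_auc / aucs[sample])
            entry["samples"][sample] = values
        out.append(entry)
    return out
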