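"""Interval algebra and the gene annotation model.

Coordinates are 1-based closed throughout the package: an interval
``[start, end]`` includes both endpoints and has width ``end - start + 1``.
Converters at the I/O boundaries (``covquant.io``) translate BED/bedGraph
(0-based half-open) and SAM (1-based).

The central construction is the *disjoint exon*: a maximal window of exonic
sequence lying in a constant subset of a gene's exons.  Summing per-base
coverage over a gene's disjoint exons counts every exonic base exactly once,
even when transcripts of the gene share exon sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GtfRecord",
    "disjoin_intervals",
    "merge_intervals",
    "build_gene_model",
    "strip_gene_version",
]

#: Strand value meaning "not specified" (GFF/BED use "." for the same idea).
UNSTRANDED = "."

_VALID_STRANDS = {"+", "-", UNSTRANDED}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contig-anchored 1-based closed coordinate range.

    The universal unit for exons, aligned blocks, junctions and expressed
    regions.  Ordering is (contig, start, end, strand), which gives the
    deterministic feature order used in every output table.
    """

    contig: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("interval contig must be non-empty")
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(_VALID_STRANDS)}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely inside this interval (same contig)."""
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_width(self, other: "GenomicInterval") -> int:
        """Number of bases shared with *other* (0 if different contigs)."""
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def padded(self, pad: int, contig_length: int | None = None) -> "GenomicInterval":
        """Symmetric padding by *pad* bases, clipped to [1, contig_length]."""
        start = max(1, self.start - pad)
        end = self.end + pad
        if contig_length is not None:
            end = min(end, contig_length)
        return GenomicInterval(self.contig, start, end, self.strand)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


def _check_single_contig(intervals: Sequence[GenomicInterval]) -> None:
    contigs = {iv.contig for iv in intervals}
    if len(contigs) > 1:
        a, b = sorted(contigs)[:2]
        raise ValueError(
            f"intervals span multiple contigs (found {a!r} and {b!r}); "
            "disjoin operates on a single contig"
        )


def disjoin_intervals(
    intervals: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Split overlapping intervals into disjoint pieces with constant membership.

    Returns the minimal set of non-overlapping intervals such that every
    output interval is contained in exactly the same subset of inputs at
    every base.  Outputs are sorted by start; their union equals the union
    of the inputs, base for base.  Strand is carried over when all inputs
    covering a piece agree, otherwise dropped to unspecified.

    Examples
    --------
    >>> ivs = [GenomicInterval("seq", 1, 5), GenomicInterval("seq", 1, 8),
    ...        GenomicInterval("seq", 13, 15)]
    >>> [(d.start, d.end) for d in disjoin_intervals(ivs)]
    [(1, 5), (6, 8), (13, 15)]
    """
    if not intervals:
        return []
    _check_single_contig(intervals)
    contig = intervals[0].contig

    # Breakpoints where the covering subset can change: every input start and
    # every position just past an input end.  Adjacent atoms always differ in
    # membership, so no post-merge is needed.
    breakpoints = sorted(
        {iv.start for iv in intervals} | {iv.end + 1 for iv in intervals}
    )
    out: list[GenomicInterval] = []
    for lo, hi in zip(breakpoints, breakpoints[1:]):
        atom_start, atom_end = lo, hi - 1
        covering = [
            iv for iv in intervals if iv.start <= atom_start and atom_end <= iv.end
        ]
        if not covering:
            continue
        strands = {iv.strand for iv in covering}
        strand = strands.pop() if len(strands) == 1 else UNSTRANDED
        out.append(GenomicInterval(contig, atom_start, atom_end, strand))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of maximal non-overlapping pieces.

    Adjacent (bookended) intervals are merged; strand is not preserved.
    Accepts intervals from several contigs; output sorted by (contig, start).
    """
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    out: list[GenomicInterval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + 1:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(contig, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(contig, cur_start, cur_end))
    return out


def strip_gene_version(gene_id: str) -> str:
    """Drop the version suffix of a versioned gene ID.

    Removes the first ``.`` and everything after it, keeping only the stable
    Ensembl part of a Gencode-style ID.  Idempotent.

    >>> strip_gene_version("ENSG00000000003.14")
    'ENSG00000000003'
    """
    if not gene_id:
        raise ValueError("gene_id must be non-empty")
    return gene_id.split(".", 1)[0]


@dataclass
class GtfRecord:
    """One annotation record as parsed from GTF/GFF2."""

    contig: str
    feature: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str]
    line_number: int = 0


@dataclass
class GeneModel:
    """Genes -> transcripts -> exons, with derived disjoint exons.

    Attributes
    ----------
    genes
        gene_id -> set of transcript ids.
    transcripts
        transcript_id -> exons sorted by (start, end).
    gene_exons
        gene_id -> the gene's unique exons (deduplicated across transcripts),
        sorted by (start, end); indices into this list define exon identity
        for membership and exon-count recomposition.
    disjoint_exons
        gene_id -> non-overlapping intervals covering exactly the gene's
        exonic bases, sorted by start.
    membership
        gene_id -> per disjoint exon, the set of indices (into
        ``gene_exons[gene_id]``) of the exons containing it.
    exonic_union
        contig -> merged exonic intervals across all genes.
    """

    genes: dict[str, set[str]] = field(default_factory=dict)
    transcripts: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    gene_exons: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    disjoint_exons: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    membership: dict[str, list[frozenset[int]]] = field(default_factory=dict)
    exonic_union: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    gene_contig: dict[str, str] = field(default_factory=dict)
    gene_strand: dict[str, str] = field(default_factory=dict)

    def gene_span(self, gene_id: str) -> GenomicInterval:
        """Smallest interval containing all exons of the gene."""
        exons = self.gene_exons[gene_id]
        return GenomicInterval(
            self.gene_contig[gene_id],
            min(e.start for e in exons),
            max(e.end for e in exons),
            self.gene_strand.get(gene_id, UNSTRANDED),
        )

    def implied_introns(self) -> set[tuple[str, int, int]]:
        """Introns implied by consecutive exons of every transcript.

        Keyed by (contig, first skipped base, last skipped base); spliced
        alignments whose skipped interval matches one of these are
        *annotated* junctions.  Strand is deliberately ignored: the model
        allows unstranded annotation and unstranded alignments.
        """
        introns: set[tuple[str, int, int]] = set()
        for exons in self.transcripts.values():
            for left, right in zip(exons, exons[1:]):
                if right.start > left.end + 1:
                    introns.add((left.contig, left.end + 1, right.start - 1))
        return introns

    def validate(self) -> None:
        """Check the structural invariants of the model (used by tests)."""
        for gid, djs in self.disjoint_exons.items():
            for a, b in zip(djs, djs[1:]):
                if b.start <= a.end:
                    raise AssertionError(f"gene {gid}: disjoint exons overlap")
            union_exons = merge_intervals(self.gene_exons[gid])
            union_djs = merge_intervals(djs) if djs else []
            if union_exons != union_djs:
                raise AssertionError(f"gene {gid}: disjoint exons != exon union")
            for dj, members in zip(djs, self.membership[gid]):
                for idx in members:
                    if not self.gene_exons[gid][idx].contains(dj):
                        raise AssertionError(
                            f"gene {gid}: disjoint exon {dj} not inside exon {idx}"
                        )


def build_gene_model(records: Iterable[GtfRecord]) -> GeneModel:
    """Assemble a :class:`GeneModel` from annotation records.

    Only records with feature type ``exon`` contribute.  Exons shared
    verbatim by two transcripts of one gene are deduplicated before the
    disjoin; exons shared by two *genes* are kept per gene, so gene counts
    may double-count bases shared across genes (the disjoin only guards
    against double counting within a gene).

    Raises
    ------
    ValueError
        If an exon record lacks ``gene_id``/``transcript_id`` (message names
        the line number), or if no exon records are present.
    """
    model = GeneModel()
    for rec in records:
        if rec.feature != "exon":
            continue
        gene_id = rec.attributes.get("gene_id")
        if not gene_id:
            raise ValueError(
                f"exon record at line {rec.line_number} lacks a gene_id attribute"
            )
        tx_id = rec.attributes.get("transcript_id")
        if not tx_id:
            raise ValueError(
                f"exon record at line {rec.line_number} lacks a transcript_id attribute"
            )
        strand = rec.strand if rec.strand in _VALID_STRANDS else UNSTRANDED
        exon = GenomicInterval(rec.contig, rec.start, rec.end, strand)
        model.genes.setdefault(gene_id, set()).add(tx_id)
        model.transcripts.setdefault(tx_id, []).append(exon)
        if gene_id in model.gene_contig and model.gene_contig[gene_id] != rec.contig:
            raise ValueError(
                f"gene {gene_id!r} has exons on contigs "
                f"{model.gene_contig[gene_id]!r} and {rec.contig!r}"
            )
        model.gene_contig[gene_id] = rec.contig
        model.gene_strand.setdefault(gene_id, strand)

    if not model.genes:
        raise ValueError("annotation contains no exon records")

    for tx_id in model.transcripts:
        model.transcripts[tx_id].sort(key=lambda iv: (iv.start, iv.end))

    all_exons: list[GenomicInterval] = []
    for gene_id, tx_ids in model.genes.items():
        seen: set[tuple[int, int]] = set()
        unique: list[GenomicInterval] = []
        for tx_id in sorted(tx_ids):
            for exon in model.transcripts[tx_id]:
                key = (exon.start, exon.end)
                if key not in seen:
                    seen.add(key)
                    unique.append(exon)
        unique.sort(key=lambda iv: (iv.start, iv.end))
        model.gene_exons[gene_id] = unique
        djs = disjoin_intervals(unique)
        model.disjoint_exons[gene_id] = djs
        model.membership[gene_id] = [
            frozenset(i for i, e in enumerate(unique) if e.contains(dj)) for dj in djs
        ]
        all_exons.extend(unique)

    for iv in merge_intervals(all_exons):
        model.exonic_union.setdefault(iv.contig, []).append(iv)
    return model
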