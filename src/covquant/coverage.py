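"""Aligned reads -> per-contig base-pair coverage curves.

The coverage curve records, at every base of the genome, how many aligned
read blocks overlap that base.  Soft-clipped bases are excluded (they did
not align) and spliced gaps (CIGAR ``N``) are excluded (the read skips the
reference there); deletions (``D``) remain covered, since they are
reference-consuming alignment, not splicing.

Coverage is stored run-length encoded: genomes are mostly flat stretches,
and every downstream operation (AUC, feature sums, thresholding) works
directly on runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import GenomicInterval

__all__ = [
    "AlignedSegment",
    "CoverageVector",
    "blocks_from_cigar",
    "coverage_from_alignments",
    "auc",
]

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")

# reference-consuming ops that leave the base covered
_COVERED_OPS = frozenset("M=XD")


def blocks_from_cigar(
    pos: int, cigar: str
) -> tuple[list[tuple[int, int]], int, list[tuple[int, int]]]:
    """Expand a CIGAR string into aligned blocks, clip count and junctions.

    Parameters
    ----------
    pos
        1-based reference position of the first aligned base.
    cigar
        CIGAR with operators M, =, X, I, D, N, S, H (P accepted, no-op).

    Returns
    -------
    blocks
        Sorted, non-overlapping ``(start, end)`` 1-based closed reference
        intervals covered by the alignment.  ``M``/``=``/``X`` and ``D``
        consume reference and are covered; consecutive covered ops merge
        into one block.
    clipped_bases
        Total soft/hard clipped bases (``S`` + ``H``); never covered.
    junctions
        One ``(start, end)`` interval per ``N`` op: the skipped reference
        bases of a spliced alignment.

    Raises
    ------
    ValueError
        On a malformed CIGAR, echoing the offending text.
    """
    if not cigar or cigar == "*":
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    consumed = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        consumed += len(m.group(0))
    if consumed != len(cigar):
        bad = cigar[consumed:] if consumed < len(cigar) else cigar
        raise ValueError(f"malformed CIGAR token: {bad!r} in {cigar!r}")

    blocks: list[tuple[int, int]] = []
    junctions: list[tuple[int, int]] = []
    clipped = 0
    ref = pos  # next reference base to consume
    block_start: int | None = None
    for m in _CIGAR_TOKEN.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if n == 0:
            raise ValueError(f"malformed CIGAR token: {m.group(0)!r} in {cigar!r}")
        if op in _COVERED_OPS:
            if block_start is None:
                block_start = ref
            ref += n
        elif op == "N":
            if block_start is not None:
                blocks.append((block_start, ref - 1))
                block_start = None
            junctions.append((ref, ref + n - 1))
            ref += n
        elif op in "SH":
            clipped += n
        # I and P consume nothing on the reference
    if block_start is not None:
        blocks.append((block_start, ref - 1))
    return blocks, clipped, junctions


@dataclass(frozen=True)
class AlignedSegment:
    """One aligned read (or mate): its covered reference blocks.

    ``blocks`` are sorted and non-overlapping; gaps between consecutive
    blocks are the spliced (CIGAR ``N``) junction intervals and are exposed
    via :meth:`junctions`.  Paired-end mates are independent segments.
    """

    read_id: str
    contig: str
    blocks: tuple[GenomicInterval, ...]
    clipped_bases: int = 0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"segment {self.read_id!r} has no aligned blocks")
        if self.clipped_bases < 0:
            raise ValueError("clipped_bases must be >= 0")
        for b in self.blocks:
            if b.contig != self.contig:
                raise ValueError(
                    f"segment {self.read_id!r}: block on {b.contig!r}, "
                    f"segment on {self.contig!r}"
                )
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"segment {self.read_id!r}: blocks overlap or are unsorted"
                )

    @property
    def aligned_bases(self) -> int:
        return sum(b.width for b in self.blocks)

    def junctions(self) -> list[GenomicInterval]:
        """Skipped reference intervals between consecutive blocks."""
        return [
            GenomicInterval(self.contig, a.end + 1, b.start - 1)
            for a, b in zip(self.blocks, self.blocks[1:])
            if b.start > a.end + 1
        ]


def segment_from_cigar(
    read_id: str, contig: str, pos: int, cigar: str
) -> AlignedSegment:
    """Convenience constructor: parse *cigar* and build an AlignedSegment."""
    blocks, clipped, _ = blocks_from_cigar(pos, cigar)
    return AlignedSegment(
        read_id,
        contig,
        tuple(GenomicInterval(contig, s, e) for s, e in blocks),
        clipped,
    )


class CoverageVector:
    """Run-length-encoded non-negative coverage over positions ``1..length``.

    ``values[i]`` holds the coverage of the ``i``-th run and ``lengths[i]``
    its number of bases; run lengths sum to ``length``.  Values are integer
    for raw coverage and float for scaled or mean tracks.
    """

    __slots__ = ("contig", "values", "lengths", "length")

    def __init__(
        self,
        contig: str,
        values: Sequence[float] | np.ndarray,
        lengths: Sequence[int] | np.ndarray,
    ) -> None:
        self.contig = contig
        self.values = np.asarray(values)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        if self.values.shape != self.lengths.shape or self.values.ndim != 1:
            raise ValueError("values and lengths must be 1-D and equal length")
        if self.values.size and (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")
        if self.values.size and (self.lengths < 1).any():
            raise ValueError("run lengths must be >= 1")
        self.length = int(self.lengths.sum())
        if self.length == 0:
            raise ValueError("coverage vector must span at least one base")

    # ---- constructors -------------------------------------------------

    @classmethod
    def zeros(cls, contig: str, length: int) -> "CoverageVector":
        return cls(contig, [0], [length])

    @classmethod
    def from_dense(
        cls, contig: str, dense: Sequence[float] | np.ndarray
    ) -> "CoverageVector":
        dense = np.asarray(dense)
        if dense.size == 0:
            raise ValueError("dense coverage must span at least one base")
        change = np.flatnonzero(dense[1:] != dense[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [dense.size]))
        return cls(contig, dense[starts], ends - starts)

    # ---- views --------------------------------------------------------

    def to_dense(self) -> np.ndarray:
        return np.repeat(self.values, self.lengths)

    def runs(self) -> Iterable[tuple[int, int, float]]:
        """Yield (start, end, value) per run, 1-based closed."""
        pos = 1
        for v, n in zip(self.values.tolist(), self.lengths.tolist()):
            yield pos, pos + n - 1, v
            pos += n

    def slice(self, start: int, end: int) -> np.ndarray:
        """Dense per-base coverage over ``[start, end]`` (1-based closed)."""
        if start < 1 or end > self.length or end < start:
            raise ValueError(
                f"slice [{start}, {end}] outside contig {self.contig!r} "
                f"of length {self.length}"
            )
        bounds = np.concatenate(([0], np.cumsum(self.lengths)))  # 0-based run edges
        i = np.searchsorted(bounds, start - 1, side="right") - 1
        j = np.searchsorted(bounds, end - 1, side="right") - 1
        pieces = []
        for k in range(i, j + 1):
            lo = max(start - 1, bounds[k])
            hi = min(end, bounds[k + 1])
            pieces.append(np.full(int(hi - lo), self.values[k]))
        return np.concatenate(pieces)

    def region_sum(self, start: int, end: int) -> float:
        """Sum of coverage over ``[start, end]`` without densifying."""
        if start < 1 or end > self.length or end < start:
            raise ValueError(
                f"range [{start}, {end}] outside contig {self.contig!r} "
                f"of length {self.length}"
            )
        bounds = np.concatenate(([0], np.cumsum(self.lengths)))
        i = np.searchsorted(bounds, start - 1, side="right") - 1
        j = np.searchsorted(bounds, end - 1, side="right") - 1
        total = 0.0
        for k in range(i, j + 1):
            lo = max(start - 1, bounds[k])
            hi = min(end, bounds[k + 1])
            total += float(self.values[k]) * (hi - lo)
        return total

    # ---- arithmetic ---------------------------------------------------

    @property
    def auc(self) -> float:
        """Area under the coverage curve: sum of value x run length."""
        return float(np.dot(self.values, self.lengths))

    def scaled(self, factor: float) -> "CoverageVector":
        """Pointwise multiplication; returns a new (float) vector."""
        return CoverageVector(
            self.contig, self.values.astype(float) * factor, self.lengths.copy()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageVector):
            return NotImplemented
        return (
            self.contig == other.contig
            and self.length == other.length
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.lengths, other.lengths)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CoverageVector({self.contig!r}, length={self.length}, "
            f"runs={self.values.size}, auc={self.auc:g})"
        )


def coverage_from_alignments(
    segments: Iterable[AlignedSegment],
    contig_lengths: Mapping[str, int],
) -> dict[str, CoverageVector]:
    """Per-contig coverage: value at base b = number of blocks containing b.

    Every aligned block base contributes exactly once; clipped bases and
    spliced gaps contribute nothing.  Contigs with no alignments get an
    all-zero vector, so the result always spans the whole genome.

    Raises
    ------
    ValueError
        If a block lies beyond its contig's stated length, or on a contig
        absent from *contig_lengths*.
    """
    deltas: dict[str, np.ndarray] = {
        contig: np.zeros(int(length) + 1, dtype=np.int64)
        for contig, length in contig_lengths.items()
    }
    for seg in segments:
        delta = deltas.get(seg.contig)
        if delta is None:
            raise ValueError(
                f"segment {seg.read_id!r} on unknown contig {seg.contig!r}"
            )
        length = contig_lengths[seg.contig]
        for b in seg.blocks:
            if b.end > length:
                raise ValueError(
                    f"block {b.start}-{b.end} of segment {seg.read_id!r} "
                    f"exceeds contig {seg.contig!r} length {length}"
                )
            delta[b.start - 1] += 1
            delta[b.end] -= 1
    return {
        contig: CoverageVector.from_dense(contig, np.cumsum(delta[:-1]))
        for contig, delta in deltas.items()
    }


def auc(coverage: CoverageVector | Mapping[str, CoverageVector]) -> float:
    """Total area under coverage, summed over every base of every contig."""
    if isinstance(coverage, CoverageVector):
        return coverage.auc
    return float(sum(cv.auc for cv in coverage.values()))
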