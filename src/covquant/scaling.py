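"""Library-size scaling of coverage counts and coverage tracks.

Coverage counts are sums of base-level coverage, so their magnitude grows
with sequencing depth and read length.  Two linear rescalings bring them
onto a common "reads at a target library size" scale:

* AUC scaling:      scaled = count / AUC * target
* mapped scaling:   scaled = count / (read_length * mapped) * target

where AUC (area under coverage) is the total coverage summed over every
base of the genome.  Without soft clipping or spliced gaps the two agree,
because then AUC == mapped reads x read length; with clipping, AUC is the
more precise denominator (clipped bases never reached the genome).

Scaled gene-count column sums never exceed the target: exonic coverage is
a subset of all coverage, so sum(gene counts) <= AUC, and the deficit is
the reads (equivalents) that did not overlap exonic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .coverage import CoverageVector
from .quantify import CountMatrix

__all__ = [
    "SampleInfo",
    "ScalingParams",
    "scale_counts_auc",
    "scale_counts_mapped",
    "scale_count_matrix",
    "scale_coverage_track",
]

#: Default target library size, in reads.
DEFAULT_TARGET_READS = 40_000_000

#: Default target AUC for track scaling: 40 million 100-bp reads.
DEFAULT_TARGET_AUC = 40_000_000 * 100


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample library statistics needed for scaling.

    ``avg_read_length`` is the sum of mate lengths for paired-end samples
    (mates are counted as independent segments throughout the package).
    """

    sample_id: str
    mapped_read_count: int
    avg_read_length: float
    auc: float
    paired_end: bool = False

    def __post_init__(self) -> None:
        if self.auc > self.mapped_read_count * self.avg_read_length + 1e-9:
            raise ValueError(
                f"sample {self.sample_id!r}: auc ({self.auc}) exceeds "
                "mapped_read_count x avg_read_length; clipping can only "
                "remove bases"
            )


@dataclass(frozen=True)
class ScalingParams:
    """How to scale: target library size (reads), method, rounding."""

    target: float = DEFAULT_TARGET_READS
    method: str = "auc"
    round: bool = False

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise ValueError("target library size must be positive")
        if self.method not in ("auc", "mapped"):
            raise ValueError(f"unknown scaling method {self.method!r}")


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest, halves away from zero (documented tie rule)."""
    arr = np.asarray(x, dtype=float)
    rounded = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    return float(rounded) if np.isscalar(x) or arr.ndim == 0 else rounded


def scale_counts_auc(counts, auc: float, target: float, round: bool = False):
    """Scale coverage counts by area under coverage: c -> c / auc * target.

    *target* is a library size in reads.  Results are generally not
    integers; pass ``round=True`` to round half-away-from-zero.

    Raises
    ------
    ValueError
        If ``auc`` is not positive (scaling undefined).
    """
    if auc <= 0:
        raise ValueError("auc must be positive for scaling")
    scaled = np.asarray(counts, dtype=float) / auc * target
    if round:
        scaled = _round_half_away(scaled)
    if np.ndim(counts) == 0:
        return float(scaled)
    return scaled


def scale_counts_mapped(
    counts, read_length: float, mapped: int, target: float, round: bool = False
):
    """Scale coverage counts by mapped reads x read length (the pre-AUC
    denominator): c -> c / (read_length * mapped) * target.

    Raises
    ------
    ValueError
        If ``read_length * mapped`` is not positive.
    """
    denom = read_length * mapped
    if denom <= 0:
        raise ValueError("read_length x mapped must be positive for scaling")
    scaled = np.asarray(counts, dtype=float) / denom * target
    if round:
        scaled = _round_half_away(scaled)
    if np.ndim(counts) == 0:
        return float(scaled)
    return scaled


def scale_count_matrix(
    matrix: CountMatrix,
    samples: Mapping[str, SampleInfo],
    params: ScalingParams = ScalingParams(),
) -> CountMatrix:
    """Column-wise scaling of a count matrix to the target library size."""
    values = np.empty(matrix.values.shape, dtype=float)
    for s, sample_id in enumerate(matrix.sample_ids):
        try:
            info = samples[sample_id]
        except KeyError:
            raise KeyError(f"no sample info for {sample_id!r}") from None
        col = matrix.values[:, s]
        if params.method == "auc":
            values[:, s] = scale_counts_auc(col, info.auc, params.target)
        else:
            values[:, s] = scale_counts_mapped(
                col, info.avg_read_length, info.mapped_read_count, params.target
            )
    if params.round:
        values = _round_half_away(values)
    return CountMatrix(
        list(matrix.feature_ids),
        list(matrix.intervals),
        list(matrix.sample_ids),
        values,
        kind=matrix.kind,
        scaled=True,
    )


def scale_coverage_track(
    coverage: CoverageVector | Mapping[str, CoverageVector],
    auc: float,
    target_auc: float = DEFAULT_TARGET_AUC,
):
    """Rescale a coverage track so its genome-wide AUC becomes *target_auc*.

    Pointwise multiplication by ``target_auc / auc``; *auc* must be the
    track's own total AUC for the post-condition (scaled AUC == target)
    to hold.  Accepts a single vector or a contig -> vector mapping.
    """
    if auc <= 0:
        raise ValueError("auc must be positive for track scaling")
    factor = target_auc / auc
    if isinstance(coverage, CoverageVector):
        return coverage.scaled(factor)
    return {contig: cv.scaled(factor) for contig, cv in coverage.items()}
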