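"""Shared fixtures and independent brute-force oracles.

The oracles deliberately take the dumbest possible route (per-base loops
over dense arrays) so they share no code path with the run-length-encoded
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from covquant import GenomicInterval, make_toy_fixture


@pytest.fixture(scope="session")
def toy():
    return make_toy_fixture()


@pytest.fixture(scope="session")
def toy_cov(toy):
    return toy.coverage()["seq"]


# --------------------------------------------------------------------------
# brute-force oracles
# --------------------------------------------------------------------------

def disjoin_oracle(intervals: list[GenomicInterval]) -> list[tuple[int, int]]:
    """Label every base with its covering input subset; merge equal runs."""
    if not intervals:
        return []
    contig = intervals[0].contig
    hi = max(iv.end for iv in intervals)
    labels = [frozenset(i for i, iv in enumerate(intervals)
                        if iv.start <= b <= iv.end)
              for b in range(1, hi + 1)]
    out: list[tuple[int, int]] = []
    start = None
    for b, lab in enumerate(labels + [frozenset()], start=1):
        prev = labels[b - 2] if b >= 2 else frozenset()
        if lab != prev:
            if start is not None and prev:
                out.append((start, b - 1))
            start = b if lab else None
    return out


def coverage_oracle(blocks: list[tuple[int, int]], length: int) -> np.ndarray:
    """Per-base loop: count blocks containing each base."""
    dense = np.zeros(length, dtype=np.int64)
    for b in range(1, length + 1):
        dense[b - 1] = sum(1 for s, e in blocks if s <= b <= e)
    return dense


def regions_oracle(dense: np.ndarray, cutoff: float, max_gap: int):
    """Naive base scan: above-cutoff runs with value/area and cluster ids."""
    expressed = dense > cutoff
    raw: list[tuple[int, int]] = []
    start = None
    for b in range(1, len(dense) + 1):
        if expressed[b - 1] and start is None:
            start = b
        elif not expressed[b - 1] and start is not None:
            raw.append((start, b - 1))
            start = None
    if start is not None:
        raw.append((start, len(dense)))
    out = []
    clusters: list[list[int]] = []
    for i, (s, e) in enumerate(raw):
        if clusters and s - raw[clusters[-1][-1]][1] - 1 <= max_gap:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    cluster_of = {}
    span_of = {}
    for cid, members in enumerate(clusters, start=1):
        span = raw[members[-1]][1] - raw[members[0]][0] + 1
        for i in members:
            cluster_of[i] = cid
            span_of[i] = span
    for i, (s, e) in enumerate(raw):
        seg = dense[s - 1 : e]
        out.append(
            dict(start=s, end=e, value=float(seg.mean()), area=float(seg.sum()),
                 cluster=cluster_of[i], cluster_length=span_of[i])
        )
    return out


def random_intervals(rng: np.random.Generator, n: int, length: int,
                     contig: str = "c") -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        s = int(rng.integers(1, length + 1))
        e = min(length, s + int(rng.integers(0, max(2, length // 4))))
        out.append(GenomicInterval(contig, s, e))
    return out
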