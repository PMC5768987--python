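"""Genomic interval model and strand-aware coordinate operations.

All coordinates are 0-based half-open (BED arithmetic) throughout the
package; 1-based inclusive coordinates appear only at RepeatMasker ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Length of the intersection in bp (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Gap distance in bp; 0 if overlapping or adjacent; None across chroms."""
        if self.chrom != other.chrom:
            return None
        return max(0, self.start - other.end, other.start - self.end)


@dataclass(frozen=True)
class TEElement:
    """A transposable-element copy with repeat taxonomy labels.

    ``subfamily`` is the RepeatMasker repeat name (e.g. LTR7, SVA_D),
    ``family`` the repeat family (HERVH, HERVK, SVA, L1, ...), ``class_``
    the repeat class (LTR, LINE, SINE, ...).
    """

    interval: GenomicInterval
    subfamily: str
    family: str
    class_: str
    element_id: str

    def __post_init__(self) -> None:
        if not self.family or not self.class_:
            raise ValueError(f"{self.element_id}: family and class_ must be non-empty")

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class Peak:
    """A peak interval (ChIP or ATAC) with a non-negative score."""

    interval: GenomicInterval
    score: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("peak score must be >= 0")


# Promoter convention: TSS -2000/+500 bp, strand aware.  Recorded in all
# output metadata; the window is a package convention, configurable here.
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500


def promoter_of(
    interval: GenomicInterval,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> GenomicInterval:
    """Promoter window around the TSS, strand aware, clipped at 0."""
    if interval.strand == "-":
        start, end = interval.end - downstream, interval.end + upstream
    else:
        start, end = interval.start - upstream, interval.start + downstream
    return GenomicInterval(interval.chrom, max(0, start), max(1, end), interval.strand)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"{self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"{self.gene_id}: exon outside gene interval")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = ex.end

    @property
    def promoter(self) -> GenomicInterval:
        return promoter_of(self.interval)

    @property
    def strand(self) -> str:
        return self.interval.strand

    def three_prime_exon(self) -> GenomicInterval:
        """The 3'-most exon in transcription order (strand aware)."""
        return self.exons[0] if self.strand == "-" else self.exons[-1]


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff a and b share the chromosome and intersect by >= min_bp."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return a.overlap_bp(b) >= min_bp


class IntervalIndex:
    """Per-chromosome vectorized overlap and nearest-feature queries.

    Ties in nearest-feature queries are broken deterministically by
    (smaller start, then lexicographically smaller id).
    """

    def __init__(self, intervals: Sequence[GenomicInterval], ids: Sequence[str] | None = None):
        if ids is None:
            ids = [str(i) for i in range(len(intervals))]
        if len(ids) != len(intervals):
            raise ValueError("ids and intervals length mismatch")
        self.intervals = list(intervals)
        self.ids = list(ids)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by: dict[str, list[int]] = {}
        for i, iv in enumerate(self.intervals):
            by.setdefault(iv.chrom, []).append(i)
        for chrom, idxs in by.items():
            idx = np.asarray(idxs)
            starts = np.asarray([self.intervals[i].start for i in idxs])
            ends = np.asarray([self.intervals[i].end for i in idxs])
            self._by_chrom[chrom] = (starts, ends, idx)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, query: GenomicInterval, min_bp: int = 1) -> list[int]:
        """Indices of stored intervals overlapping query by >= min_bp."""
        if query.chrom not in self._by_chrom:
            return []
        starts, ends, idx = self._by_chrom[query.chrom]
        ov = np.minimum(ends, query.end) - np.maximum(starts, query.start)
        return [int(i) for i in idx[ov >= min_bp]]

    def any_overlap(self, query: GenomicInterval, min_bp: int = 1) -> bool:
        if query.chrom not in self._by_chrom:
            return False
        starts, ends, idx = self._by_chrom[query.chrom]
        ov = np.minimum(ends, query.end) - np.maximum(starts, query.start)
        return bool((ov >= min_bp).any())

    def nearest(self, query: GenomicInterval, max_dist: int) -> tuple[int, int] | None:
        """(index, gap distance) of nearest feature within max_dist, or None."""
        if query.chrom not in self._by_chrom:
            return None
        starts, ends, idx = self._by_chrom[query.chrom]
        gaps = np.maximum(0, np.maximum(starts - query.end, query.start - ends))
        best = gaps.min()
        if best > max_dist:
            return None
        cand = np.flatnonzero(gaps == best)
        # deterministic tie-break: smaller start, then lexicographic id
        key = sorted(cand, key=lambda j: (int(starts[j]), self.ids[int(idx[j])]))
        j = key[0]
        return int(idx[j]), int(best)


def nearest_feature(
    query: GenomicInterval,
    features: Sequence[GenomicInterval],
    max_dist: int,
    ids: Sequence[str] | None = None,
) -> tuple[GenomicInterval, int] | None:
    """Nearest feature by gap distance (0 if overlapping) within max_dist."""
    res = IntervalIndex(features, ids).nearest(query, max_dist)
    if res is None:
        return None
    i, d = res
    return features[i], d


@dataclass(frozen=True)
class AnchorBins:
    """Ordered element-anchored bins in 5'->3' biological orientation."""

    bins: tuple[tuple[int, int], ...]
    chrom: str
    clipped: bool


def anchor_bins(
    element: TEElement | GenomicInterval,
    flank_bp: int = 5000,
    body_bins: int = 50,
    flank_bins: int = 25,
) -> AnchorBins:
    """Bins covering [5' flank | scaled body | 3' flank] of an element.

    Returns ``flank_bins`` fixed-width upstream bins, ``body_bins``
    equal-fraction body bins tiling the element exactly, and
    ``flank_bins`` downstream bins, ordered 5'->3' in element orientation:
    bin 0 is always biologically upstream.  Coordinates below 0 are
    clipped and the result flagged.
    """
    iv = element.interval if isinstance(element, TEElement) else element
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    if iv.length < body_bins:
        raise ValueError(
            f"element length {iv.length} < body_bins {body_bins}; caller should skip"
        )
    length = iv.length
    up = [
        (iv.start - flank_bp + round(i * flank_bp / flank_bins),
         iv.start - flank_bp + round((i + 1) * flank_bp / flank_bins))
        for i in range(flank_bins)
    ]
    body = [
        (iv.start + round(i * length / body_bins),
         iv.start + round((i + 1) * length / body_bins))
        for i in range(body_bins)
    ]
    down = [
        (iv.end + round(i * flank_bp / flank_bins),
         iv.end + round((i + 1) * flank_bp / flank_bins))
        for i in range(flank_bins)
    ]
    genomic = up + body + down
    clipped = genomic[0][0] < 0
    genomic = [(max(0, s), max(1, e)) for s, e in genomic]
    if iv.strand == "-":
        genomic = genomic[::-1]
    return AnchorBins(bins=tuple(genomic), chrom=iv.chrom, clipped=clipped)
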