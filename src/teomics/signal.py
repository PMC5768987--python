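"""Step-function signal tracks (bedGraph) with exact window averages.

A :class:`SignalTrack` stores, per chromosome, sorted non-overlapping
intervals with numeric values; positions not covered by any interval
evaluate to 0.  Window means are computed exactly from a precomputed
cumulative integral, so queries are O(log n).
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np


class SignalTrack:
    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        """data: chrom -> (starts, ends, values), sorted and non-overlapping."""
        self._data = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping intervals on {chrom}")
            if np.any(starts >= ends):
                raise ValueError(f"empty interval on {chrom}")
            # cumulative integral of signal up to each interval start
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._data[chrom] = (starts, ends, values, cum)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            by.setdefault(chrom, []).append((int(start), int(end), float(value)))
        data = {}
        for chrom, rows in by.items():
            rows.sort()
            s, e, v = zip(*rows)
            data[chrom] = (np.array(s), np.array(e), np.array(v))
        return cls(data)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def intervals(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom, (starts, ends, values, _) in self._data.items():
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal value at a single position (0 where uncovered)."""
        if chrom not in self._data:
            return 0.0
        starts, ends, values, _ = self._data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Integral of the signal over [start, end), uncovered bases as 0."""
        if end <= start:
            raise ValueError("require start < end")
        if chrom not in self._data:
            return 0.0
        starts, ends, values, cum = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        total = cum[hi] - cum[lo]
        # trim partial overlap at both edges
        if starts[lo] < start:
            total -= values[lo] * (start - starts[lo])
        if ends[hi - 1] > end:
            total -= values[hi - 1] * (ends[hi - 1] - end)
        return float(total)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over [start, end) with uncovered bases counted as 0."""
        return self.integral(chrom, start, end) / (end - start)

    def covered_bp(self) -> int:
        return int(sum((e - s).sum() for s, e, _, _ in self._data.values()))

    def covered_mean(self) -> float:
        """Mean value over covered positions only."""
        bp = self.covered_bp()
        if bp == 0:
            return 0.0
        tot = sum(float(c[-1]) for _, _, _, c in self._data.values())
        return tot / bp

    def normalized(self) -> "SignalTrack":
        """Track scaled so the mean over covered positions is 1."""
        m = self.covered_mean()
        if m == 0:
            return self
        return SignalTrack(
            {c: (s.copy(), e.copy(), v / m) for c, (s, e, v, _) in self._data.items()}
        )

    def __add__(self, other: "SignalTrack") -> "SignalTrack":
        """Pointwise sum of two step functions."""
        data = {}
        for chrom in set(self.chroms) | set(other.chroms):
            pieces = []
            for trk in (self, other):
                if chrom in trk._data:
                    s, e, v, _ = trk._data[chrom]
                    pieces.append((s, e, v))
            if len(pieces) == 1:
                data[chrom] = pieces[0]
                continue
            bounds = np.unique(np.concatenate([np.concatenate([s, e]) for s, e, _ in pieces]))
            seg_s, seg_e = bounds[:-1], bounds[1:]
            total = np.zeros(len(seg_s))
            for s, e, v in pieces:
                # value of this piece on each elementary segment
                i = np.searchsorted(s, seg_s, side="right") - 1
                ok = (i >= 0) & (seg_s < e[np.clip(i, 0, len(e) - 1)])
                total[ok] += v[i[ok]]
            keep = total != 0
            data[chrom] = (seg_s[keep], seg_e[keep], total[keep])
        return SignalTrack(data)
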