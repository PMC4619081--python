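"""Piecewise-constant signal tracks (bedGraph / bigWig).

A :class:`SignalTrack` holds per-chromosome sorted, non-overlapping segments
with float values.  Positions not covered by any segment have value 0, so
every genomic interval is queryable; queries outside the recorded extent of
a chromosome are valid and 0-valued.
"""

from __future__ import annotations

import numpy as np


class SignalTrack:
    """Interval-queryable non-negative signal over a genome."""

    def __init__(self, segments: dict):
        """``segments`` maps chrom -> (starts, ends, values) numpy arrays,
        sorted by start and non-overlapping."""
        self._data = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping segments on {chrom}")
            self._data[chrom] = (starts, ends, values)

    @classmethod
    def from_bedgraph(cls, path) -> "SignalTrack":
        segs: dict = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#", "browser")):
                    continue
                chrom, start, end, value = line.split()[:4]
                segs.setdefault(chrom, []).append(
                    (int(start), int(end), float(value))
                )
        return cls(
            {
                chrom: tuple(np.array(col) for col in zip(*rows))
                for chrom, rows in segs.items()
            }
        )

    @classmethod
    def from_bigwig(cls, path) -> "SignalTrack":
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(str(path))
        try:
            segs = {}
            for chrom in bw.chroms():
                ivals = bw.intervals(chrom)
                if ivals:
                    s, e, v = zip(*ivals)
                    segs[chrom] = (np.array(s), np.array(e), np.array(v))
            return cls(segs)
        finally:
            bw.close()

    @classmethod
    def constant(cls, chrom_sizes: dict, value: float) -> "SignalTrack":
        return cls(
            {
                c: (np.array([0]), np.array([size]), np.array([value]))
                for c, size in chrom_sizes.items()
            }
        )

    def chroms(self):
        return list(self._data)

    def chrom_length(self, chrom) -> int:
        """Recorded extent: end of the last segment (0 if chrom unknown)."""
        if chrom not in self._data:
            return 0
        return int(self._data[chrom][1][-1])

    def mean(self, chrom, start, end) -> float:
        """Arithmetic mean of per-base values over [start, end)."""
        if end <= start:
            raise ValueError("interval length must be >= 1")
        return self._overlap_sum(chrom, start, end) / (end - start)

    def _overlap_sum(self, chrom, start, end) -> float:
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(ov, values[lo:hi]))

    def values(self, chrom, start, end) -> np.ndarray:
        """Per-base values over [start, end); uncovered positions are 0."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._data:
            return out
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            out[max(s, start) - start : max(min(e, end) - start, 0)] = v
        return out

    def binned_means(self, chrom, start, end, n_bins) -> np.ndarray:
        """Mean value per bin over [start, end) split into equal bins."""
        edges = np.linspace(start, end, n_bins + 1).round().astype(int)
        return np.array(
            [self.mean(chrom, s, e) if e > s else 0.0 for s, e in zip(edges[:-1], edges[1:])]
        )

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._data):
                starts, ends, values = self._data[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def load_track(path) -> SignalTrack:
    """Load a signal track, dispatching on file extension."""
    p = str(path)
    if p.endswith((".bw", ".bigwig", ".bigWig")):
        return SignalTrack.from_bigwig(p)
    return SignalTrack.from_bedgraph(p)
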