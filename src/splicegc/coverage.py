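"""Stepwise coverage tracks (ChIP/MNase/RNAPII signal).

Tracks are stored densely per chromosome; positions never written read as
zero, matching the bedGraph convention that absent intervals carry no
signal.
"""

from __future__ import annotations

import numpy as np

from .intervals import GenomicInterval


class CoverageTrack:
    def __init__(self, arrays: dict[str, np.ndarray] | None = None):
        self._arrays: dict[str, np.ndarray] = arrays or {}

    @property
    def chroms(self) -> list[str]:
        return list(self._arrays)

    def chrom_array(self, chrom: str) -> np.ndarray:
        return self._arrays.get(chrom, np.zeros(0))

    def set_chrom(self, chrom: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if (values < 0).any():
            raise ValueError("coverage must be non-negative")
        self._arrays[chrom] = values

    def values(self, interval: GenomicInterval) -> np.ndarray:
        """Depth per position over [start, end) in transcript orientation.

        Positions outside the stored array read as 0.
        """
        arr = self._arrays.get(interval.chrom)
        out = np.zeros(len(interval), dtype=float)
        if arr is not None:
            lo = max(interval.start, 0)
            hi = min(interval.end, len(arr))
            if hi > lo:
                out[lo - interval.start : hi - interval.start] = arr[lo:hi]
        if interval.strand == "-":
            out = out[::-1]
        return out

    # -- bedGraph round-trip ------------------------------------------------

    @classmethod
    def from_bedgraph(cls, path, chrom_sizes: dict[str, int] | None = None) -> "CoverageTrack":
        arrays: dict[str, np.ndarray] = {}
        rows: list[tuple[str, int, int, float]] = []
        max_end: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                chrom, start, end, value = line.split("\t")
                start, end, value = int(start), int(end), float(value)
                rows.append((chrom, start, end, value))
                max_end[chrom] = max(max_end.get(chrom, 0), end)
        if chrom_sizes:
            for chrom, size in chrom_sizes.items():
                max_end[chrom] = max(max_end.get(chrom, 0), size)
        for chrom, size in max_end.items():
            arrays[chrom] = np.zeros(size, dtype=float)
        for chrom, start, end, value in rows:
            arrays[chrom][start:end] = value
        return cls(arrays)

    def to_bedgraph(self, path) -> None:
        """Write runs of constant non-zero value; zero runs are omitted."""
        with open(path, "w") as fh:
            for chrom in sorted(self._arrays):
                arr = self._arrays[chrom]
                if arr.size == 0:
                    continue
                change = np.nonzero(np.diff(arr))[0] + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0.0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
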