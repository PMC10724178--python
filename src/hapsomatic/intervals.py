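"""Genomic intervals and window tiling.

All interval arithmetic in this package is 0-based half-open. Every
user-facing report (BED round-trips excepted, which are natively 0-based)
converts to 1-based inclusive coordinates, e.g. the window starting at
0-based 95_700_000 of length 100 kb is printed ``chr1:95700001-95800000``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def report(self) -> str:
        """1-based inclusive display form (``chrom:start+1-end``)."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    @classmethod
    def from_report(cls, text: str) -> "GenomicInterval":
        """Inverse of :meth:`report`; the round-trip is lossless."""
        chrom, _, span = text.rpartition(":")
        lo, _, hi = span.partition("-")
        return cls(chrom, int(lo) - 1, int(hi))


def tile_windows(
    chrom_lengths: dict[str, int], window_size: int = 100_000
) -> list[GenomicInterval]:
    """Tile each chromosome into non-overlapping fixed-size windows.

    Tiles are aligned to multiples of ``window_size``; a terminal partial
    tile keeps its true (shorter) length. Window order follows the input
    chromosome order, then position.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows: list[GenomicInterval] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        for start in range(0, length, window_size):
            windows.append(GenomicInterval(chrom, start, min(start + window_size, length)))
    return windows


def window_index_of(pos: int, window_size: int) -> int:
    """Tile index of a 0-based position; boundaries are unambiguous
    because tiles are half-open."""
    return pos // window_size
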