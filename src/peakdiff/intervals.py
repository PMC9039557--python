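"""Genomic intervals, BED IO and the merged union peak universe.

All coordinates are 0-based half-open (BED convention).  The union peak set
is the shared quantification universe: every sample's peak calls are pooled,
sorted and merged (overlapping *or* book-ended intervals collapse into one)
so that the result is pairwise disjoint and each fragment midpoint can land
in at most one peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """Sorted, pairwise-disjoint intervals defining the quantification universe.

    Chromosomes are ordered lexicographically; within a chromosome intervals
    are sorted by start and strictly separated (no overlap, no abutment).
    """

    intervals: list[GenomicInterval]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev: GenomicInterval | None = None
        for iv in self.intervals:
            if prev is not None:
                if (prev.chrom, prev.start) > (iv.chrom, iv.start):
                    raise ValueError("PeakSet intervals must be sorted by (chrom, start)")
                if prev.chrom == iv.chrom and prev.end >= iv.start:
                    raise ValueError(
                        f"PeakSet intervals must be disjoint and non-abutting: "
                        f"{prev.chrom}:{prev.start}-{prev.end} vs {iv.start}-{iv.end}"
                    )
            prev = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    @property
    def lengths(self):
        import numpy as np

        return np.array([len(iv) for iv in self.intervals], dtype=float)

    def names(self) -> list[str]:
        return [
            iv.name if iv.name is not None else f"peak_{i}"
            for i, iv in enumerate(self.intervals)
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": self.names(),
            }
        )


_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 intervals; header/track/comment lines are skipped.

    Columns beyond the fourth are discarded (scores from upstream peak
    callers are not used — peaks are re-quantified from the alignments).
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-delimited columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "" else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not intervals:
        warnings.warn(f"{path}: no intervals found", stacklevel=2)
    return intervals


def merge_union(
    interval_lists: Iterable[Sequence[GenomicInterval]],
    provenance: Sequence[str] | None = None,
) -> PeakSet:
    """Pool interval lists into a sorted, merged, disjoint union peak set.

    Intervals that overlap by >=1 bp or abut (end == next start) are merged,
    so the output covers exactly the same bases as the input union.
    """
    pooled = [iv for lst in interval_lists for iv in lst]
    pooled.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for iv in pooled:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_chrom is not None:
                merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_chrom is not None:
        merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    named = [
        GenomicInterval(iv.chrom, iv.start, iv.end, f"peak_{i}")
        for i, iv in enumerate(merged)
    ]
    return PeakSet(named, provenance=list(provenance) if provenance else [])


def write_bed(peaks: PeakSet | Sequence[GenomicInterval], path: str | Path) -> Path:
    """Write intervals as BED4 (name = peak_<index> when absent)."""
    path = Path(path)
    intervals = list(peaks)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = iv.name if iv.name is not None else f"peak_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
    return path
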