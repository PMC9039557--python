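"""Read counting over the union peak set: library size, FRiP and RPKM.

A *qualifying* record is mapped, primary (neither secondary nor
supplementary), not flagged as a duplicate, and has mapping quality at or
above a uniqueness threshold (default 20) — the operational definition of
"uniquely mapped" used throughout.  For properly paired reads only the
first mate is counted so that a sequenced fragment contributes exactly one
unit both to the library size and to at most one peak.

Fragments are assigned to peaks by their midpoint: the template-span
midpoint for proper pairs, the read midpoint for single-end records.
Because the peak universe is disjoint, the midpoint rule guarantees that no
fragment is ever counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from peakdiff.intervals import PeakSet

DEFAULT_MIN_MAPQ = 20


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal alignment record: coordinates, quality and SAM-flag booleans."""

    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    mapq: int
    unmapped: bool = False
    secondary: bool = False
    supplementary: bool = False
    duplicate: bool = False
    paired: bool = False
    proper_pair: bool = False
    first_in_pair: bool = False
    template_length: int = 0

    def qualifies(self, min_mapq: int = DEFAULT_MIN_MAPQ) -> bool:
        """Whether this record contributes one fragment to the library."""
        if self.unmapped or self.secondary or self.supplementary or self.duplicate:
            return False
        if self.mapq < min_mapq:
            return False
        if self.paired:
            # only proper pairs form a fragment; count it once via mate 1
            return self.proper_pair and self.first_in_pair
        return True

    @property
    def fragment_midpoint(self) -> int:
        if self.paired and self.proper_pair:
            tlen = self.template_length
            if tlen >= 0:
                frag_start, frag_end = self.start, self.start + tlen
            else:
                frag_start, frag_end = self.end + tlen, self.end
            return (frag_start + frag_end) // 2
        return (self.start + self.end) // 2


def iter_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM or BAM file (pysam-backed)."""
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                yield AlignmentRecord(
                    chrom="*", start=0, end=1, mapq=rec.mapping_quality, unmapped=True
                )
                continue
            yield AlignmentRecord(
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end
                if rec.reference_end is not None
                else rec.reference_start + 1,
                mapq=rec.mapping_quality,
                secondary=rec.is_secondary,
                supplementary=rec.is_supplementary,
                duplicate=rec.is_duplicate,
                paired=rec.is_paired,
                proper_pair=rec.is_proper_pair,
                first_in_pair=rec.is_read1,
                template_length=rec.template_length,
            )


def _as_records(alignments) -> Iterable[AlignmentRecord]:
    if isinstance(alignments, (str, Path)):
        return iter_alignments(alignments)
    return alignments


def library_size(alignments, min_mapq: int = DEFAULT_MIN_MAPQ) -> int:
    """Number of qualifying fragments (the sequencing-depth denominator)."""
    n = 0
    for rec in _as_records(alignments):
        if rec.qualifies(min_mapq):
            n += 1
    if n == 0:
        raise ValueError("empty library: no qualifying alignments")
    return n


class _PeakIndex:
    """Per-chromosome sorted start/end arrays for O(log n) midpoint lookup."""

    def __init__(self, peaks: PeakSet):
        self.offsets: dict[str, int] = {}
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for i, iv in enumerate(peaks):
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self.offsets.setdefault(iv.chrom, i)
        for chrom, spans in by_chrom.items():
            arr = np.asarray(spans, dtype=np.int64)
            self.starts[chrom] = arr[:, 0]
            self.ends[chrom] = arr[:, 1]

    def find(self, chrom: str, pos: int) -> int:
        """Index of the peak containing pos, or -1."""
        starts = self.starts.get(chrom)
        if starts is None:
            return -1
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        if j >= 0 and pos < self.ends[chrom][j]:
            return self.offsets[chrom] + j
        return -1


def count_reads(
    alignments,
    peaks: PeakSet,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    check_sorted: bool = True,
) -> tuple[np.ndarray, int, int]:
    """Count fragments per peak by midpoint assignment.

    Returns (per-peak counts, in-peak total, library size).  The alignment
    stream must be coordinate-sorted; paired and single-end records may not
    be mixed within one stream.
    """
    index = _PeakIndex(peaks)
    counts = np.zeros(len(peaks), dtype=np.int64)
    lib = 0
    seen_paired = seen_single = False
    prev_chrom: str | None = None
    prev_start = -1
    done_chroms: set[str] = set()
    for rec in _as_records(alignments):
        if check_sorted and not rec.unmapped:
            if rec.chrom != prev_chrom:
                if rec.chrom in done_chroms:
                    raise ValueError("alignment stream is not coordinate-sorted")
                if prev_chrom is not None:
                    done_chroms.add(prev_chrom)
                prev_chrom, prev_start = rec.chrom, rec.start
            elif rec.start < prev_start:
                raise ValueError("alignment stream is not coordinate-sorted")
            else:
                prev_start = rec.start
        if not rec.qualifies(min_mapq):
            continue
        if rec.paired:
            seen_paired = True
        else:
            seen_single = True
        if seen_paired and seen_single:
            raise ValueError("mixed single-end and paired-end records in one sample")
        lib += 1
        j = index.find(rec.chrom, rec.fragment_midpoint)
        if j >= 0:
            counts[j] += 1
    if lib == 0:
        raise ValueError("empty library: no qualifying alignments")
    return counts, int(counts.sum()), lib


@dataclass
class CountMatrix:
    """Integer fragment counts over the union peak set, peaks x samples."""

    peaks: PeakSet
    samples: list[str]
    counts: np.ndarray  # (n_peaks, n_samples) int
    library_sizes: np.ndarray  # (n_samples,) int
    in_peak_totals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.shape != (len(self.peaks), len(self.samples)):
            raise ValueError("counts shape does not match peaks x samples")
        if np.any(self.library_sizes <= 0):
            raise ValueError("library sizes must be positive")
        if self.in_peak_totals is None:
            self.in_peak_totals = self.counts.sum(axis=0)
        self.in_peak_totals = np.asarray(self.in_peak_totals, dtype=np.int64)
        if np.any(self.in_peak_totals > self.library_sizes):
            raise ValueError("in-peak totals exceed library sizes")

    @property
    def frip(self) -> np.ndarray:
        return self.in_peak_totals / self.library_sizes

    def to_frame(self):
        import pandas as pd

        df = self.peaks.to_frame()
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        return df


def count_matrix(
    alignment_paths: Mapping[str, str | Path],
    peaks: PeakSet,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> CountMatrix:
    """Quantify several samples' alignment files over one peak universe."""
    samples = list(alignment_paths)
    cols, libs, totals = [], [], []
    for s in samples:
        c, t, lib = count_reads(alignment_paths[s], peaks, min_mapq=min_mapq)
        cols.append(c)
        libs.append(lib)
        totals.append(t)
    return CountMatrix(
        peaks=peaks,
        samples=samples,
        counts=np.column_stack(cols),
        library_sizes=np.asarray(libs),
        in_peak_totals=np.asarray(totals),
    )


def count_sample(
    path: str | Path, peaks: PeakSet, min_mapq: int = DEFAULT_MIN_MAPQ
) -> tuple[np.ndarray, int, int]:
    """Single-sample convenience wrapper around :func:`count_reads`."""
    return count_reads(path, peaks, min_mapq=min_mapq)


def rpkm(counts: CountMatrix) -> np.ndarray:
    """Reads per kilobase of peak per million mapped reads.

    rpkm[i, j] = counts[i, j] / ((length_i / 1e3) * (library_size_j / 1e6))
    """
    lengths = counts.peaks.lengths
    if np.any(lengths <= 0):
        raise ValueError("peak lengths must be positive")
    if np.any(counts.library_sizes <= 0):
        raise ValueError("library sizes must be positive")
    denom = np.outer(lengths / 1e3, counts.library_sizes / 1e6)
    return counts.counts / denom


def frip(counts: CountMatrix) -> np.ndarray:
    """Fraction of (uniquely mapped) reads in peaks, per sample."""
    return counts.frip
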