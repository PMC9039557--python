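"""Copy-number segments (IGV .seg dialect) and per-peak copy-ratio factors.

Copy-number alterations inflate read counts independently of any epigenetic
change, so peaks inside amplified regions look spuriously "differential".
The correction converts segment log2 ratios into per-peak, per-sample copy
ratios (overlap-length-weighted mean of 2**log2_ratio, uncovered bases
neutral at 1.0) and multiplies them into the per-sample size factors to
form a peaks-x-samples normalization-factor matrix.  The factors enter the
negative-binomial mean model directly; raw integer counts are never
rescaled, which keeps the NB likelihood valid.

.seg files follow the IGV convention: tab-delimited with a header, columns
Sample, Chromosome, Start, End, [Num_Probes,] Segment_Mean, coordinates
1-based inclusive on disk (converted to 0-based half-open in memory), and
Segment_Mean interpreted as log2(copy number / 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from peakdiff.intervals import PeakSet
from peakdiff.normalize import SizeFactors

RATIO_FLOOR = 0.05  # deep deletions are floored to avoid factor blow-ups


@dataclass(frozen=True)
class CnvSegment:
    """One copy-number segment; coordinates 0-based half-open in memory."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment start must precede end: {self}")
        if not math.isfinite(self.log2_ratio):
            raise ValueError(f"segment log2 ratio must be finite: {self}")


def read_seg(path: str | Path) -> list[CnvSegment]:
    """Parse an IGV .seg file into segments.

    The last column is taken as Segment_Mean, accommodating both 5-column
    and 6-column (with Num_Probes) dialects.  Overlapping segments within a
    sample are rejected.
    """
    path = Path(path)
    segments: list[CnvSegment] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 tab-delimited columns")
            sample, chrom = fields[0], fields[1]
            try:
                start1, end1 = int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                mean = float(fields[-1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric Segment_Mean") from exc
            try:
                segments.append(CnvSegment(sample, chrom, start1 - 1, end1, mean))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    _check_disjoint(segments)
    return segments


def _check_disjoint(segments: Iterable[CnvSegment]) -> None:
    by_key: dict[tuple[str, str], list[CnvSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping segments for sample {sample} on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def write_seg(segments: Sequence[CnvSegment], path: str | Path) -> Path:
    """Write segments back to the IGV dialect (1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for seg in segments:
            fh.write(
                f"{seg.sample_id}\t{seg.chrom}\t{seg.start + 1}\t{seg.end}\t"
                f"0\t{seg.log2_ratio:.12g}\n"
            )
    return path


def copy_ratio_per_peak(
    segments: Sequence[CnvSegment],
    peaks: PeakSet,
    sample_ids: Sequence[str],
    ratio_floor: float = RATIO_FLOOR,
) -> np.ndarray:
    """Per-peak, per-sample copy ratios (peaks x samples).

    ratio[i, j] is the overlap-length-weighted mean of 2**log2_ratio over
    sample j's segments intersecting peak i, with uncovered bases
    contributing 1.0.  Samples without segments get an all-1 column.
    Ratios are floored at ``ratio_floor``.
    """
    _check_disjoint(segments)
    ratios = np.ones((len(peaks), len(sample_ids)), dtype=float)
    col = {s: j for j, s in enumerate(sample_ids)}
    by_key: dict[tuple[str, str], list[CnvSegment]] = {}
    for seg in segments:
        if seg.sample_id in col:
            by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    # per (sample, chrom): sorted arrays for vectorized peak overlap
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        rvals = np.array([2.0 ** s.log2_ratio for s in segs])
        j = col[sample]
        for i, pk in enumerate(peaks):
            if pk.chrom != chrom:
                continue
            lo = int(np.searchsorted(ends, pk.start, side="right"))
            hi = int(np.searchsorted(starts, pk.end, side="left"))
            if lo >= hi:
                continue
            ov = np.minimum(ends[lo:hi], pk.end) - np.maximum(starts[lo:hi], pk.start)
            covered = float(ov.sum())
            weighted = float((ov * rvals[lo:hi]).sum())
            length = len(pk)
            ratios[i, j] = (weighted + (length - covered) * 1.0) / length
    return np.maximum(ratios, ratio_floor)


def normalization_factors(
    sf: SizeFactors, copy_ratios: np.ndarray | None, n_peaks: int | None = None
) -> np.ndarray:
    """Elementwise product of size factors and copy ratios (peaks x samples).

    With ``copy_ratios=None`` the size factors are broadcast over peaks
    (``n_peaks`` rows), i.e. the no-CNV identity.
    """
    factors = np.asarray(sf.factors, dtype=float)
    if copy_ratios is None:
        if n_peaks is None:
            raise ValueError("n_peaks required when no copy ratios are given")
        out = np.tile(factors, (n_peaks, 1))
    else:
        ratios = np.asarray(copy_ratios, dtype=float)
        if ratios.shape[1] != factors.shape[0]:
            raise ValueError("copy-ratio columns must match number of samples")
        out = ratios * factors[None, :]
    if np.any(out <= 0):
        raise ValueError("normalization factors must be strictly positive")
    return out
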