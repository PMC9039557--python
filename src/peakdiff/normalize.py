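"""Low-signal filtering, matrix normalization and per-sample size factors.

Two competing size-factor schemes are provided:

``depth``
    factor_j = library_size_j / geometric-mean(library sizes).  Because the
    fraction of reads in peaks (FRiP) varies with global occupancy, scaling
    by total uniquely mapped reads keeps truly unchanged peaks at fold
    change ~0 even when one condition gains thousands of new peaks.

``reads_in_peaks``
    DESeq2-style median-of-ratios computed on the peak count matrix: each
    sample's factor is the median over peaks of count / per-peak geometric
    mean (peaks with zero reference excluded).  When conditions differ in
    FRiP this equalizes in-peak totals and drags unchanged peaks away from
    zero fold change — the behaviour the depth scheme exists to avoid.

Both schemes are re-centred to geometric mean 1 so fold changes are
directly comparable between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class NormalizedMatrix:
    """Normalized peak-by-sample matrix plus the surviving-row mapping."""

    values: np.ndarray
    method: str  # quantile | zscore | log | filtered
    kept_index: np.ndarray  # row -> original peak row

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.kept_index = np.asarray(self.kept_index, dtype=np.int64)


@dataclass
class SizeFactors:
    """Per-sample positive scale factors with geometric mean 1."""

    scheme: str  # depth | reads_in_peaks
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("size factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError("size factors must have geometric mean 1")


def filter_low_rpkm(
    rpkm_matrix: np.ndarray, min_rpkm: float = 1.0, min_samples: int = 2
) -> NormalizedMatrix:
    """Keep peaks with RPKM >= min_rpkm in at least min_samples samples."""
    m = np.asarray(rpkm_matrix, dtype=float)
    if m.size == 0:
        raise ValueError("empty matrix")
    keep = (m >= min_rpkm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            "all peaks removed by the RPKM filter; lower min_rpkm or min_samples"
        )
    return NormalizedMatrix(
        values=m[keep], method="filtered", kept_index=np.flatnonzero(keep)
    )


def quantile_normalize(matrix: np.ndarray) -> NormalizedMatrix:
    """Classic sort–average–remap quantile normalization.

    Every column is mapped onto the reference distribution obtained by
    averaging the columns' order statistics; after the transform all columns
    share one multiset of values.  Ties within a column receive the mean of
    the reference values at their tied rank positions.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("quantile normalization requires a 2-D matrix with >=2 columns")
    n, _ = m.shape
    reference = np.sort(m, axis=0).mean(axis=1)
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        col = m[:, j]
        order = np.argsort(col, kind="stable")
        ranked_ref = np.empty(n)
        ranked_ref[order] = reference
        # average reference values over runs of tied input values
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                ranked_ref[order[s:e]] = reference[s:e].mean()
        out[:, j] = ranked_ref
    return NormalizedMatrix(values=out, method="quantile", kept_index=np.arange(n))


def transform(
    matrix: np.ndarray, method: str, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Elementwise log2(x + pseudocount) or per-row z-scoring.

    Constant rows under z-score map to all zeros rather than NaN.
    """
    m = np.asarray(matrix, dtype=float)
    if method == "log":
        if np.any(m < 0):
            raise ValueError("log transform requires non-negative values")
        values = np.log2(m + pseudocount)
    elif method == "zscore":
        mean = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, ddof=0, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        values = (m - mean) / sd
    else:
        raise ValueError(f"unknown transform {method!r}; choose 'zscore' or 'log'")
    return NormalizedMatrix(values=values, method=method, kept_index=np.arange(m.shape[0]))


def size_factors(
    count_matrix,
    scheme: str = "depth",
    library_sizes: np.ndarray | None = None,
) -> SizeFactors:
    """Per-sample size factors under the depth or reads-in-peaks scheme.

    ``count_matrix`` may be a :class:`peakdiff.counting.CountMatrix` or a
    plain (peaks x samples) array (in which case depth needs
    ``library_sizes``).
    """
    counts = getattr(count_matrix, "counts", count_matrix)
    counts = np.asarray(counts, dtype=float)
    if library_sizes is None:
        library_sizes = getattr(count_matrix, "library_sizes", None)
    if scheme == "depth":
        if library_sizes is None:
            raise ValueError("depth scheme requires library sizes")
        libs = np.asarray(library_sizes, dtype=float)
        if np.any(libs <= 0):
            raise ValueError("library sizes must be positive")
        factors = libs / np.exp(np.mean(np.log(libs)))
    elif scheme == "reads_in_peaks":
        if not np.any(counts > 0):
            raise ValueError("all-zero count matrix")
        with np.errstate(divide="ignore"):
            log_ref = np.mean(np.log(counts), axis=1)  # -inf where any zero
        usable = np.isfinite(log_ref)
        if not usable.any():
            raise ValueError(
                "no peak has nonzero counts in every sample; "
                "median-of-ratios undefined"
            )
        ratios = np.log(counts[usable]) - log_ref[usable, None]
        factors = np.exp(np.median(ratios, axis=0))
        factors = factors / np.exp(np.mean(np.log(factors)))
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose 'depth' or 'reads_in_peaks'")
    return SizeFactors(scheme=scheme, factors=factors)
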