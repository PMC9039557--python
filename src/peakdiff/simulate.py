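"""Synthetic ChIP/ATAC-seq experiment generator with ground truth.

The simulator draws per-peak, per-sample fragment counts from a negative
binomial whose mean encodes condition structure, copy number and
sequencing depth, then (optionally) materializes the experiment as
coordinate-sorted SAM alignments, per-sample peak BEDs, IGV .seg files and
a metadata sheet.  Fragment midpoints are placed strictly inside their
peak and background midpoints strictly outside every peak, so midpoint
counting recovers the drawn counts exactly and the fraction of reads in
peaks (FRiP) is controlled sharply.

Two mean models are available:

* shared/gained (default): every condition carries ``n_shared_peaks`` at a
  common per-depth intensity; the ``gaining_condition`` additionally
  carries ``n_gained_peaks`` at full strength, which all other conditions
  see only at a small basal level.  Peak intensities are solved from the
  per-condition FRiP targets so that shared peaks are exactly non-
  differential on the per-depth scale — the configuration under which
  depth scaling is correct and in-peak scaling misbehaves.
* archetypes: peak classes with per-condition relative profiles,
  renormalized per condition to the FRiP target (time-course designs).

Copy-number blocks multiply the NB mean of overlapping peaks in affected
samples on top of the FRiP-derived baseline (amplification adds reads), and
are emitted as .seg segments so the correction can be tested against truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from peakdiff.counting import CountMatrix
from peakdiff.cnv import CnvSegment, copy_ratio_per_peak, write_seg
from peakdiff.intervals import GenomicInterval, PeakSet, write_bed


@dataclass
class CnvBlock:
    chrom: str
    start: int
    end: int
    copy_ratio: float  # multiplicative on counts; emitted as log2(copy_ratio)
    condition: str


@dataclass
class Archetype:
    name: str
    n_peaks: int
    profile: dict[str, float]  # condition -> relative weight


@dataclass
class SimulationConfig:
    """Complete description of one synthetic experiment."""

    seed: int
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    conditions: list[str] = field(default_factory=lambda: ["A", "B"])
    replicates: dict[str, int] = field(default_factory=lambda: {"A": 2, "B": 2})
    n_shared_peaks: int = 1000
    n_gained_peaks: int = 0
    gaining_condition: str | None = None
    gained_basal_mean: float = 3.0  # expected fragments/gained peak elsewhere
    peak_length: tuple[int, int] = (200, 400)
    fragments_per_sample: int = 200_000
    target_frip: dict[str, float] = field(default_factory=lambda: {"A": 0.1, "B": 0.1})
    nb_dispersion: float = 0.02
    effect_log2_fc: float = 0.0  # applied to n_differential shared peaks
    n_differential: int = 0
    cnv_blocks: list[CnvBlock] = field(default_factory=list)
    archetypes: list[Archetype] | None = None
    read_length: int = 50
    paired: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for c, f in self.target_frip.items():
            if not 0 < f < 1:
                raise ValueError(f"target FRiP for {c} must be in (0, 1)")
        if self.fragments_per_sample <= 0 or self.n_shared_peaks < 0:
            raise ValueError("counts must be positive")
        if self.n_gained_peaks > 0 and self.gaining_condition is None:
            raise ValueError("gained peaks require a gaining_condition")

    def scaled(self, factor: float) -> "SimulationConfig":
        """Same experiment at reduced depth (per-peak means scale by factor)."""
        cfg = dataclasses.replace(
            self,
            fragments_per_sample=max(int(self.fragments_per_sample * factor), 1000),
            gained_basal_mean=self.gained_basal_mean * factor,
        )
        return cfg

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{c}_rep{r + 1}" for c in self.conditions for r in range(self.replicates[c])
        ]

    def condition_of(self, sample_id: str) -> str:
        return sample_id.rsplit("_rep", 1)[0]


@dataclass
class TruthTable:
    """Ground truth: per-peak class/effect/copy ratio and per-sample stats."""

    peaks: pd.DataFrame  # name, chrom, start, end, peak_class, true_log2_fc, cnv_<cond>
    samples: pd.DataFrame  # sample_id, condition, library_size, realized_frip

    def write(self, outdir: Path) -> tuple[Path, Path]:
        p1 = outdir / "truth_peaks.tsv"
        p2 = outdir / "truth_samples.tsv"
        self.peaks.to_csv(p1, sep="\t", index=False)
        self.samples.to_csv(p2, sep="\t", index=False)
        return p1, p2

    @classmethod
    def read(cls, outdir: Path) -> "TruthTable":
        return cls(
            peaks=pd.read_csv(outdir / "truth_peaks.tsv", sep="\t"),
            samples=pd.read_csv(outdir / "truth_samples.tsv", sep="\t"),
        )


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    peak_set: PeakSet
    counts: CountMatrix
    truth: TruthTable
    means: np.ndarray  # NB means used for the draws (peaks x samples)
    segments: list[CnvSegment]
    peak_classes: np.ndarray  # per-peak class label
    sample_conditions: list[str]

    def sample_peak_mask(self, sample_id: str) -> np.ndarray:
        """Which peaks appear in this sample's BED (gained only when gaining)."""
        cond = self.config.condition_of(sample_id)
        mask = self.peak_classes != "gained"
        if cond == self.config.gaining_condition:
            mask = np.ones(len(self.peak_classes), dtype=bool)
        return mask


def _place_peaks(cfg: SimulationConfig, rng: np.random.Generator) -> PeakSet:
    """Non-overlapping peaks placed uniformly, clear of chromosome edges."""
    n_arch = sum(a.n_peaks for a in cfg.archetypes) if cfg.archetypes else 0
    n_total = cfg.n_shared_peaks + cfg.n_gained_peaks + n_arch
    margin = cfg.read_length + 1
    chroms = sorted(cfg.chromosomes)
    lengths = np.array([cfg.chromosomes[c] - 2 * margin for c in chroms], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("chromosomes shorter than twice the read length")
    probs = lengths / lengths.sum()
    chrom_of = rng.choice(len(chroms), size=n_total, p=probs)
    plens = rng.integers(cfg.peak_length[0], cfg.peak_length[1] + 1, size=n_total)
    intervals: list[GenomicInterval] = []
    gap = 10
    for ci, chrom in enumerate(chroms):
        idx = np.flatnonzero(chrom_of == ci)
        if len(idx) == 0:
            continue
        these = plens[idx]
        space = cfg.chromosomes[chrom] - 2 * margin - int(these.sum()) - gap * len(idx)
        if space <= 0:
            raise ValueError("not enough genome to place the requested peaks")
        # classic stars-and-bars placement of non-overlapping intervals
        offsets = np.sort(rng.integers(0, space + 1, size=len(idx)))
        pos = margin + offsets + np.concatenate(([0], np.cumsum(these[:-1] + gap)))
        for s, ln in zip(pos, these):
            intervals.append(GenomicInterval(chrom, int(s), int(s + ln)))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    named = [
        GenomicInterval(iv.chrom, iv.start, iv.end, f"peak_{i}")
        for i, iv in enumerate(intervals)
    ]
    return PeakSet(named)


def _assign_classes(
    cfg: SimulationConfig, n_peaks: int, rng: np.random.Generator
) -> np.ndarray:
    labels: list[str] = ["shared"] * cfg.n_shared_peaks + ["gained"] * cfg.n_gained_peaks
    if cfg.archetypes:
        for a in cfg.archetypes:
            labels += [a.name] * a.n_peaks
    if cfg.n_differential > 0:
        if cfg.n_differential > cfg.n_shared_peaks:
            raise ValueError("n_differential exceeds n_shared_peaks")
        for i in range(cfg.n_differential):
            labels[i] = "differential"
    arr = np.array(labels)
    rng.shuffle(arr)
    return arr


def _mean_matrix(
    cfg: SimulationConfig,
    peak_classes: np.ndarray,
    copy_ratios: np.ndarray,
    sample_conditions: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """NB means (peaks x samples) and the per-peak true log2 fold change."""
    n_peaks = len(peak_classes)
    n = float(cfg.fragments_per_sample)
    per_cond_fraction = np.zeros((n_peaks, len(cfg.conditions)))
    true_lfc = np.zeros(n_peaks)

    if cfg.archetypes:
        weights = {a.name: a.profile for a in cfg.archetypes}
        for ci, cond in enumerate(cfg.conditions):
            w = np.array([weights[cl].get(cond, 0.0) for cl in peak_classes])
            if w.sum() <= 0:
                raise ValueError(f"no peak weight in condition {cond}")
            per_cond_fraction[:, ci] = cfg.target_frip[cond] * w / w.sum()
        true_lfc[:] = np.nan  # archetype designs have no single contrast truth
    else:
        shared_like = np.isin(peak_classes, ["shared", "differential"])
        gained = peak_classes == "gained"
        n_shared = int(shared_like.sum())
        basal_fraction = cfg.gained_basal_mean / n
        gaining = cfg.gaining_condition
        # one per-depth shared intensity common to all conditions
        non_gaining = [c for c in cfg.conditions if c != gaining]
        if gaining is not None and cfg.n_gained_peaks > 0:
            ref = non_gaining[0] if non_gaining else gaining
            u = (cfg.target_frip[ref] - cfg.n_gained_peaks * basal_fraction) / n_shared
            g = (cfg.target_frip[gaining] - n_shared * u) / cfg.n_gained_peaks
            if u <= 0 or g <= 0:
                raise ValueError(
                    "target FRiP unreachable: shared/gained intensities not positive"
                )
        else:
            frips = {cfg.target_frip[c] for c in cfg.conditions}
            if len(frips) > 1:
                raise ValueError(
                    "without gained peaks all conditions must share one target FRiP"
                )
            u = cfg.target_frip[cfg.conditions[0]] / max(n_shared, 1)
            g = 0.0
        for ci, cond in enumerate(cfg.conditions):
            frac = np.zeros(n_peaks)
            frac[shared_like] = u
            if cfg.n_gained_peaks > 0:
                frac[gained] = g if cond == gaining else basal_fraction
            per_cond_fraction[:, ci] = frac
        if cfg.n_gained_peaks > 0 and gaining is not None:
            true_lfc[gained] = np.log2(g / basal_fraction)
        if cfg.n_differential > 0 and gaining is not None:
            diff = peak_classes == "differential"
            gi = cfg.conditions.index(gaining)
            per_cond_fraction[diff, gi] *= 2.0 ** cfg.effect_log2_fc
            true_lfc[diff] = cfg.effect_log2_fc

    cond_index = {c: i for i, c in enumerate(cfg.conditions)}
    cols = [per_cond_fraction[:, cond_index[c]] * n for c in sample_conditions]
    means = np.column_stack(cols) * copy_ratios
    return means, true_lfc


def _draw_counts(
    means: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(means)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means * dispersion)
    return rng.poisson(lam)


def simulate_counts(config: SimulationConfig) -> SimulatedExperiment:
    """Draw the experiment at the count level (no files written)."""
    rng = np.random.default_rng(config.seed)
    peaks = _place_peaks(config, rng)
    classes = _assign_classes(config, len(peaks), rng)
    sample_ids = config.sample_ids
    sample_conditions = [config.condition_of(s) for s in sample_ids]

    segments: list[CnvSegment] = []
    for block in config.cnv_blocks:
        for s, cond in zip(sample_ids, sample_conditions):
            if cond == block.condition:
                segments.append(
                    CnvSegment(
                        s, block.chrom, block.start, block.end,
                        float(np.log2(block.copy_ratio)),
                    )
                )
    ratios = (
        copy_ratio_per_peak(segments, peaks, sample_ids)
        if segments
        else np.ones((len(peaks), len(sample_ids)))
    )

    means, true_lfc = _mean_matrix(config, classes, ratios, sample_conditions)
    counts = _draw_counts(means, config.nb_dispersion, rng)
    in_peak = counts.sum(axis=0)
    libs = np.full(len(sample_ids), config.fragments_per_sample, dtype=np.int64)
    if np.any(in_peak > libs):
        raise ValueError("target FRiP unreachable: in-peak draws exceed library size")

    cm = CountMatrix(
        peaks=peaks,
        samples=sample_ids,
        counts=counts,
        library_sizes=libs,
        in_peak_totals=in_peak,
    )
    peak_truth = peaks.to_frame()
    peak_truth["peak_class"] = classes
    peak_truth["true_log2_fc"] = true_lfc
    for cond in config.conditions:
        j = next(i for i, c in enumerate(sample_conditions) if c == cond)
        peak_truth[f"cnv_ratio_{cond}"] = ratios[:, j]
    sample_truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": sample_conditions,
            "library_size": libs,
            "realized_frip": in_peak / libs,
        }
    )
    return SimulatedExperiment(
        config=config,
        peak_set=peaks,
        counts=cm,
        truth=TruthTable(peaks=peak_truth, samples=sample_truth),
        means=means,
        segments=segments,
        peak_classes=classes,
        sample_conditions=sample_conditions,
    )


def _complement_space(
    peaks: PeakSet, chromosomes: dict[str, int], margin: int
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Intervals of background-eligible midpoints (outside every peak)."""
    chroms, starts, ends = [], [], []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in peaks:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(chromosomes):
        pos = margin
        stop = chromosomes[chrom] - margin
        for iv in by_chrom.get(chrom, []):
            if iv.start > pos:
                chroms.append(chrom)
                starts.append(pos)
                ends.append(min(iv.start, stop))
            pos = max(pos, iv.end)
        if pos < stop:
            chroms.append(chrom)
            starts.append(pos)
            ends.append(stop)
    return chroms, np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _write_sam(
    path: Path,
    chromosomes: dict[str, int],
    midpoints_by_chrom: dict[str, np.ndarray],
    read_length: int,
    sample_id: str,
) -> None:
    half = read_length // 2
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom in sorted(chromosomes):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{chromosomes[chrom]}\n")
        i = 0
        for chrom in sorted(chromosomes):
            mids = midpoints_by_chrom.get(chrom)
            if mids is None or len(mids) == 0:
                continue
            mids = np.sort(mids)
            for m in mids:
                start = int(m) - half  # 0-based; SAM POS is 1-based
                fh.write(
                    f"{sample_id}.{i}\t0\t{chrom}\t{start + 1}\t60\t"
                    f"{read_length}M\t*\t0\t0\t*\t*\n"
                )
                i += 1


def simulate_experiment(
    config: SimulationConfig, outdir: str | Path
) -> SimulatedExperiment:
    """Materialize a simulated experiment as files under ``outdir``.

    Writes per-sample coordinate-sorted SAM and peak BED files, .seg files
    for CNV-carrying samples, a metadata CSV, truth TSVs and a manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_counts(config)
    rng = np.random.default_rng([config.seed, 7])
    peaks = sim.peak_set
    chrom_names = [iv.chrom for iv in peaks]
    starts = np.array([iv.start for iv in peaks])
    ends = np.array([iv.end for iv in peaks])
    margin = config.read_length
    bg_chroms, bg_starts, bg_ends = _complement_space(
        peaks, config.chromosomes, margin
    )
    bg_lengths = (bg_ends - bg_starts).astype(np.int64)
    bg_cum = np.concatenate(([0], np.cumsum(bg_lengths)))
    total_bg = int(bg_cum[-1])

    manifest: dict[str, dict[str, str]] = {}
    rows = []
    for j, sample in enumerate(sim.counts.samples):
        mids: dict[str, list[np.ndarray]] = {}
        col = sim.counts.counts[:, j]
        for i in np.flatnonzero(col):
            m = rng.integers(starts[i], ends[i], size=int(col[i]))
            mids.setdefault(chrom_names[i], []).append(m)
        n_bg = int(sim.counts.library_sizes[j] - sim.counts.in_peak_totals[j])
        if n_bg > 0:
            if total_bg <= 0:
                raise ValueError("no background space left outside peaks")
            u = rng.integers(0, total_bg, size=n_bg)
            seg_idx = np.searchsorted(bg_cum, u, side="right") - 1
            pos = bg_starts[seg_idx] + (u - bg_cum[seg_idx])
            for ci in np.unique(seg_idx):
                chrom = bg_chroms[ci]
                mids.setdefault(chrom, []).append(pos[seg_idx == ci])
        merged = {c: np.concatenate(v) for c, v in mids.items()}
        sam_path = outdir / f"{sample}.sam"
        _write_sam(sam_path, config.chromosomes, merged, config.read_length, sample)
        bed_path = outdir / f"{sample}_peaks.bed"
        mask = sim.sample_peak_mask(sample)
        write_bed([iv for i, iv in enumerate(peaks) if mask[i]], bed_path)
        manifest[sample] = {"sam": sam_path.name, "bed": bed_path.name}
        rows.append(
            {
                "sample_id": sample,
                "bam": sam_path.name,  # relative to the metadata file
                "bed": bed_path.name,
                "condition": sim.sample_conditions[j],
            }
        )
    if sim.segments:
        seg_path = outdir / "cnv.seg"
        write_seg(sim.segments, seg_path)
        for r in rows:
            sample_segs = [s for s in sim.segments if s.sample_id == r["sample_id"]]
            r["seg"] = seg_path.name if sample_segs else ""
    meta = pd.DataFrame(rows)
    meta.to_csv(outdir / "metadata.csv", index=False)
    sim.truth.write(outdir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {"samples": manifest, "seed": config.seed, "files": ["metadata.csv"]},
            fh,
            indent=2,
            sort_keys=True,
        )
    return sim


def scenario_presets(name: str, seed: int = 0) -> SimulationConfig:
    """Canonical study designs for the three normalization scenarios.

    ``frip_imbalance``
        Two conditions, 2 replicates each; 3,000 shared peaks at a common
        per-depth intensity plus 12,000 peaks gained by condition B; FRiP
        0.02 (A) vs 0.10 (B).  Deep, low-dispersion libraries so that
        replicate noise sits far below the size-factor artifact.
    ``cnv_arm``
        3 vs 3 replicates, equal FRiP, zero true signal; one chromosome-arm
        block at copy ratio 3 in condition B.
    ``timecourse``
        Three stages x 2 replicates with early/middle/late peak archetypes.
    """
    if name == "frip_imbalance":
        return SimulationConfig(
            seed=seed,
            chromosomes={"chr1": 20_000_000, "chr2": 20_000_000},
            conditions=["A", "B"],
            replicates={"A": 2, "B": 2},
            n_shared_peaks=3000,
            n_gained_peaks=12000,
            gaining_condition="B",
            gained_basal_mean=3.0,
            fragments_per_sample=40_000_000,
            target_frip={"A": 0.02, "B": 0.10},
            nb_dispersion=0.002,
        )
    if name == "cnv_arm":
        return SimulationConfig(
            seed=seed,
            chromosomes={"chr1": 20_000_000, "chr2": 20_000_000},
            conditions=["A", "B"],
            replicates={"A": 3, "B": 3},
            n_shared_peaks=4000,
            n_gained_peaks=0,
            fragments_per_sample=4_000_000,
            target_frip={"A": 0.10, "B": 0.10},
            nb_dispersion=0.02,
            cnv_blocks=[CnvBlock("chr1", 0, 6_000_000, 3.0, "B")],
        )
    if name == "timecourse":
        return SimulationConfig(
            seed=seed,
            chromosomes={"chr1": 10_000_000, "chr2": 10_000_000},
            conditions=["t0", "t1", "t2"],
            replicates={"t0": 2, "t1": 2, "t2": 2},
            n_shared_peaks=0,
            n_gained_peaks=0,
            fragments_per_sample=2_000_000,
            target_frip={"t0": 0.15, "t1": 0.15, "t2": 0.15},
            nb_dispersion=0.02,
            archetypes=[
                Archetype("early", 400, {"t0": 1.0, "t1": 0.45, "t2": 0.15}),
                Archetype("middle", 400, {"t0": 0.25, "t1": 1.0, "t2": 0.25}),
                Archetype("late", 400, {"t0": 0.15, "t1": 0.45, "t2": 1.0}),
            ],
        )
    raise ValueError(f"unknown preset {name!r}; options: frip_imbalance, cnv_arm, timecourse")
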