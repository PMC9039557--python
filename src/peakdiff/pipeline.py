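"""End-to-end composition: sample sheet + run config -> output tree.

Stage order: union peaks -> counting -> RPKM -> low-signal filter ->
normalization -> unsupervised outputs -> per-comparison differential
testing (size factors x optional CNV ratios) -> summary/MA tables ->
nearest-gene scores -> pre-ranked GSEA.  The union peak set and the count
matrix are computed once and shared by all comparisons.  Every stage
writes TSV artifacts and one structured log line with an MD5 checksum of
each artifact.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from peakdiff import counting, cnv as cnvmod, enrichment, normalize, unsupervised
from peakdiff.differential import ComparisonSpec, NegativeBinomialPeakModel
from peakdiff.intervals import merge_union, read_bed, write_bed

log = logging.getLogger("peakdiff")


@dataclass
class SampleSheet:
    """Sample metadata: id, alignment path, peak path, free annotations."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "bam", "bed"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id: {dup.iloc[0]!r}")

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        """Read the CSV; relative file paths resolve against its directory."""
        path = Path(path)
        table = pd.read_csv(path, dtype=str).fillna("")
        for col in ("bam", "bed", "seg"):
            if col in table.columns:
                table[col] = [
                    p if (not p or Path(p).is_absolute()) else str(path.parent / p)
                    for p in table[col]
                ]
        return cls(table)

    def write(self, path: str | Path) -> Path:
        self.table.to_csv(path, index=False)
        return Path(path)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def annotation_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("sample_id", "bam", "bed", "seg")]

    def select(self, filt: dict[str, str] | list[str]) -> list[str]:
        """Resolve a comparison side: explicit id list or column=value filters."""
        if isinstance(filt, list):
            unknown = set(filt) - set(self.sample_ids)
            if unknown:
                raise ValueError(f"unknown sample ids: {sorted(unknown)}")
            return list(filt)
        mask = pd.Series(True, index=self.table.index)
        for col, val in filt.items():
            if col not in self.table.columns:
                raise ValueError(f"unknown metadata column {col!r}")
            mask &= self.table[col] == str(val)
        return list(self.table.loc[mask, "sample_id"])

    def validate_files(self) -> None:
        for _, row in self.table.iterrows():
            for col in ("bam", "bed", "seg"):
                p = row.get(col, "")
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"sample {row['sample_id']}: missing {col} {p}")


@dataclass
class RunConfig:
    """Flat key/value run configuration with stated defaults."""

    outdir: str = "peakdiff_out"
    seed: int = 0
    normalization: str = "quantile"  # quantile | zscore | log
    min_rpkm: float = 1.0
    min_samples: int = 2
    distance: str = "correlation_pearson"
    linkage: str = "average"
    size_factor_scheme: str = "depth"  # depth | reads_in_peaks
    cnv_correction: bool = True
    min_mapq: int = 20
    kmeans_k: int = 0  # 0 disables feature clustering
    padj_cutoffs: tuple[float, float] = (0.05, 0.01)
    fc_cutoffs: tuple[float, float] = (1.5, 2.0)
    comparisons: dict[str, dict[str, Any]] = field(default_factory=dict)
    tss: str = ""  # BED-like TSS table for nearest-gene mapping
    gmt: str = ""  # gene sets for pre-ranked GSEA
    gsea_nperm: int = 1000
    gsea_weight: float = 1.0
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("padj_cutoffs", "fc_cutoffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()[:10]


def _stage(name: str, t0: float, outputs: list[Path], **info) -> None:
    sums = {p.name: _checksum(p) for p in outputs}
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s wall=%.2fs %s outputs=%s", name, time.time() - t0, extras, sums)


def resolve_comparisons(config: RunConfig, sheet: SampleSheet) -> list[ComparisonSpec]:
    specs = []
    for name, sides in config.comparisons.items():
        treat = sheet.select(sides["treat"])
        control = sheet.select(sides["control"])
        specs.append(ComparisonSpec(name=name, treat_ids=treat, control_ids=control))
    return specs


def run_pipeline(config: RunConfig, sheet: SampleSheet) -> dict[str, Any]:
    """Run every stage; returns a dict of key artifacts and paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    try:
        result = _run_pipeline_inner(config, sheet, outdir)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    if failed_marker.exists():
        failed_marker.unlink()
    return result


def _run_pipeline_inner(config: RunConfig, sheet: SampleSheet, outdir: Path) -> dict[str, Any]:
    # pre-flight: touch every referenced file and validate comparisons
    t0 = time.time()
    sheet.validate_files()
    specs = resolve_comparisons(config, sheet)
    if config.tss and not Path(config.tss).exists():
        raise FileNotFoundError(f"missing TSS table {config.tss}")
    if config.gmt and not Path(config.gmt).exists():
        raise FileNotFoundError(f"missing GMT file {config.gmt}")
    _stage("preflight", t0, [], samples=len(sheet.sample_ids), comparisons=len(specs))

    # union peak universe
    t0 = time.time()
    beds = {r["sample_id"]: read_bed(r["bed"]) for _, r in sheet.table.iterrows()}
    peaks = merge_union(beds.values(), provenance=list(beds))
    union_path = outdir / "union_peaks.bed"
    write_bed(peaks, union_path)
    _stage("union_peaks", t0, [union_path], peaks=len(peaks))

    # counting
    t0 = time.time()
    cm = counting.count_matrix(
        {r["sample_id"]: r["bam"] for _, r in sheet.table.iterrows()},
        peaks,
        min_mapq=config.min_mapq,
    )
    counts_path = outdir / "counts.tsv"
    cm.to_frame().to_csv(counts_path, sep="\t", index=False)
    qc = pd.DataFrame(
        {
            "sample_id": cm.samples,
            "library_size": cm.library_sizes,
            "in_peak": cm.in_peak_totals,
            "frip": cm.frip,
        }
    )
    qc_path = outdir / "sample_qc.tsv"
    qc.to_csv(qc_path, sep="\t", index=False)
    _stage("counting", t0, [counts_path, qc_path])

    # RPKM, filter, normalization
    t0 = time.time()
    rpkm_mat = counting.rpkm(cm)
    filtered = normalize.filter_low_rpkm(
        rpkm_mat, min_rpkm=config.min_rpkm, min_samples=config.min_samples
    )
    if config.normalization == "quantile":
        normed = normalize.quantile_normalize(filtered.values)
    else:
        normed = normalize.transform(filtered.values, config.normalization)
    kept = filtered.kept_index
    norm_df = peaks.to_frame().iloc[kept].reset_index(drop=True)
    for j, s in enumerate(cm.samples):
        norm_df[s] = normed.values[:, j]
    norm_path = outdir / "normalized.tsv"
    norm_df.to_csv(norm_path, sep="\t", index=False)
    _stage("normalize", t0, [norm_path], kept=len(kept), method=config.normalization)

    # unsupervised
    t0 = time.time()
    corr = unsupervised.correlation_matrix(normed.values)
    dist = unsupervised.distance_matrix(normed.values, config.distance)
    clust = unsupervised.hierarchical_cluster(dist, linkage=config.linkage)
    pca_res = unsupervised.pca(normed.values)
    corr_path = outdir / "correlation.tsv"
    pd.DataFrame(corr, index=cm.samples, columns=cm.samples).to_csv(corr_path, sep="\t")
    dist_path = outdir / "distances.tsv"
    pd.DataFrame(dist, index=cm.samples, columns=cm.samples).to_csv(dist_path, sep="\t")
    pca_path = outdir / "pca_scores.tsv"
    scores = pd.DataFrame(
        pca_res.scores,
        index=cm.samples,
        columns=[f"PC{i + 1}" for i in range(pca_res.scores.shape[1])],
    )
    scores.to_csv(pca_path, sep="\t")
    var_path = outdir / "pca_variance.tsv"
    pd.DataFrame(
        {"component": scores.columns, "variance_explained": pca_res.variance_explained}
    ).to_csv(var_path, sep="\t", index=False)
    outputs = [corr_path, dist_path, pca_path, var_path]
    if config.kmeans_k >= 2:
        labels = unsupervised.kmeans_features(
            normalize.transform(normed.values, "zscore").values,
            k=config.kmeans_k,
            seed=config.seed,
        )
        lab_path = outdir / "feature_clusters.tsv"
        lab_df = norm_df[["chrom", "start", "end", "name"]].copy()
        lab_df["cluster"] = labels
        lab_df.to_csv(lab_path, sep="\t", index=False)
        outputs.append(lab_path)
    if config.plots:
        outputs += _plots_unsupervised(outdir, corr, pca_res, cm.samples)
    _stage("unsupervised", t0, outputs, order="/".join(map(str, clust.sample_order)))

    # per-comparison differential testing
    seg_paths = sorted(
        {p for p in sheet.table.get("seg", pd.Series(dtype=str)) if p}
    )
    segments = [s for p in seg_paths for s in cnvmod.read_seg(p)]
    ratios = None
    if segments and config.cnv_correction:
        ratios = cnvmod.copy_ratio_per_peak(segments, peaks, cm.samples)
    results = {}
    for spec in specs:
        t0 = time.time()
        sf = normalize.size_factors(cm, scheme=config.size_factor_scheme)
        factors = cnvmod.normalization_factors(sf, ratios, n_peaks=len(peaks))
        res = NegativeBinomialPeakModel(cm, factors, spec).fit()
        res_path = outdir / f"differential_{spec.name}.tsv"
        res.to_frame().to_csv(res_path, sep="\t", index=False)
        grid = res.summary_table(config.padj_cutoffs, config.fc_cutoffs)
        grid_path = outdir / f"summary_{spec.name}.tsv"
        grid.to_csv(grid_path, sep="\t", index=False)
        ma_path = outdir / f"ma_{spec.name}.tsv"
        res.ma_data().to_csv(ma_path, sep="\t", index=False)
        outputs = [res_path, grid_path, ma_path]

        if config.tss:
            tss = enrichment.TssTable.from_bed(config.tss)
            assign = enrichment.nearest_gene(peaks, tss)
            ranked = enrichment.gene_scores(res, assign)
            rank_path = outdir / f"ranked_genes_{spec.name}.rnk"
            enrichment.write_ranked(ranked, rank_path)
            outputs.append(rank_path)
            if config.gmt:
                sets = enrichment.read_gmt(config.gmt)
                gsea = enrichment.gsea_preranked(
                    ranked,
                    sets,
                    weight=config.gsea_weight,
                    nperm=config.gsea_nperm,
                    seed=config.seed,
                    min_size=config.gsea_min_size,
                    max_size=config.gsea_max_size,
                )
                gsea_path = outdir / f"gsea_{spec.name}.tsv"
                gsea.to_csv(gsea_path, sep="\t", index=False)
                outputs.append(gsea_path)
        if config.plots:
            outputs.append(_plot_ma(outdir, res, spec.name))
        results[spec.name] = res
        _stage(f"differential[{spec.name}]", t0, outputs, scheme=config.size_factor_scheme)
    return {
        "peaks": peaks,
        "counts": cm,
        "normalized": normed,
        "pca": pca_res,
        "clustering": clust,
        "results": results,
        "outdir": outdir,
    }


def _plots_unsupervised(outdir: Path, corr, pca_res, samples) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(corr, cmap="viridis", vmin=-1, vmax=1)
    ax.set_xticks(range(len(samples)), samples, rotation=90, fontsize=6)
    ax.set_yticks(range(len(samples)), samples, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    p = outdir / "correlation_heatmap.png"
    fig.savefig(p, dpi=100, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pca_res.scores[:, 0], pca_res.scores[:, 1])
    for i, s in enumerate(samples):
        ax.annotate(s, pca_res.scores[i, :2], fontsize=6)
    ax.set_xlabel(f"PC1 ({pca_res.variance_explained[0]:.0%})")
    ax.set_ylabel(f"PC2 ({pca_res.variance_explained[1]:.0%})")
    p = outdir / "pca.png"
    fig.savefig(p, dpi=100, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths


def _plot_ma(outdir: Path, res, name: str) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ma = res.ma_data()
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = ma["significant"].to_numpy()
    ax.scatter(np.log10(ma["base_mean"] + 1)[~sig], ma["log2_fc"][~sig], s=2, c="grey")
    ax.scatter(np.log10(ma["base_mean"] + 1)[sig], ma["log2_fc"][sig], s=2, c="red")
    ax.axhline(0, lw=0.5, c="k")
    ax.set_xlabel("log10 mean normalized count")
    ax.set_ylabel("log2 fold change")
    p = outdir / f"ma_{name}.png"
    fig.savefig(p, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return p


def parse_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet.read(path)
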