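"""Peak-to-gene assignment and pre-ranked gene-set enrichment.

Each peak is assigned to the nearest transcription start site (TSS) on its
chromosome within a distance cutoff; per gene, the assigned peak with the
largest |Wald| statistic supplies a signed score, and the resulting ranked
list feeds a classic weighted Kolmogorov–Smirnov pre-ranked GSEA with a
gene-label permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class TssTable:
    """Gene transcription start sites: gene_id, chrom, tss position, strand."""

    table: pd.DataFrame  # columns gene_id, chrom, tss, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "tss", "strand"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"TSS table needs columns {sorted(required)}")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in TSS table")
        if (self.table["tss"] < 0).any():
            raise ValueError("TSS positions must be >= 0")

    @classmethod
    def from_bed(cls, path: str | Path) -> "TssTable":
        """Read a BED-like table: chrom, start, end, gene_id, [score,] strand.

        The TSS is the start for + genes and the end - 1 for - genes.
        """
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                strand = f[5] if len(f) > 5 else (f[4] if len(f) > 4 and f[4] in "+-" else "+")
                start, end = int(f[1]), int(f[2])
                rows.append(
                    {
                        "gene_id": f[3],
                        "chrom": f[0],
                        "tss": start if strand == "+" else end - 1,
                        "strand": strand,
                    }
                )
        return cls(pd.DataFrame(rows))


def nearest_gene(
    peaks, tss: TssTable, max_distance: int = 100_000
) -> pd.DataFrame:
    """Assign each peak to the nearest TSS within ``max_distance``.

    Returns a DataFrame indexed like the peak set with columns ``gene_id``
    (None when unassigned) and ``distance`` (signed: positive when the peak
    midpoint lies downstream of the TSS in the gene's orientation).  Ties
    in absolute distance break by lexicographic gene_id.
    """
    if len(tss.table) == 0:
        raise ValueError("empty TSS table")
    by_chrom: dict[str, pd.DataFrame] = {
        c: g.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for c, g in tss.table.groupby("chrom")
    }
    gene_ids: list[str | None] = []
    distances: list[float] = []
    warned: set[str] = set()
    for pk in peaks:
        genes = by_chrom.get(pk.chrom)
        if genes is None:
            if pk.chrom not in warned:
                import warnings

                warnings.warn(f"no TSS on chromosome {pk.chrom}", stacklevel=2)
                warned.add(pk.chrom)
            gene_ids.append(None)
            distances.append(np.nan)
            continue
        mid = pk.midpoint
        absd = (genes["tss"] - mid).abs().to_numpy()
        best = np.flatnonzero(absd == absd.min())
        if len(best) > 1:
            ids = genes["gene_id"].to_numpy()[best]
            pick = best[np.argsort(ids, kind="stable")[0]]
        else:
            pick = best[0]
        if absd[pick] > max_distance:
            gene_ids.append(None)
            distances.append(np.nan)
            continue
        row = genes.iloc[int(pick)]
        signed = mid - int(row["tss"])
        if row["strand"] == "-":
            signed = -signed
        gene_ids.append(str(row["gene_id"]))
        distances.append(float(signed))
    return pd.DataFrame({"gene_id": gene_ids, "distance": distances})


def gene_scores(results, assignments: pd.DataFrame) -> pd.DataFrame:
    """Signed per-gene scores: each gene takes its max-|Wald| assigned peak.

    ``results`` may be a DifferentialPeakResults or anything with a ``wald``
    array.  Returns a two-column frame (gene_id, score) sorted by
    descending score, ties broken by gene_id.
    """
    wald = np.asarray(getattr(results, "wald", results), dtype=float)
    df = assignments.copy().reset_index(drop=True)
    df["wald"] = wald
    df = df.dropna(subset=["gene_id", "wald"])
    if df.empty:
        raise ValueError("no peak is assigned to any gene")
    idx = df.groupby("gene_id")["wald"].apply(lambda s: s.abs().idxmax())
    scores = df.loc[idx.to_numpy(), ["gene_id", "wald"]].rename(columns={"wald": "score"})
    scores = scores.sort_values(
        ["score", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return scores


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"GMT line with <3 fields: {f[0] if f else ''!r}")
            sets[f[0]] = [g for g in f[2:] if g]
    return sets


def enrichment_score(
    ranked_scores: np.ndarray, member_mask: np.ndarray, weight: float = 1.0
) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    Hits increment proportionally to |score|**weight (normalized over set
    members); misses decrement by 1/(N - set size).
    """
    n = len(ranked_scores)
    m = int(member_mask.sum())
    if m == 0 or m == n:
        raise ValueError("gene set must be a proper non-empty subset of the list")
    weights = np.abs(ranked_scores) ** weight
    hit_total = weights[member_mask].sum()
    if hit_total == 0:
        hit = np.where(member_mask, 1.0 / m, 0.0)
    else:
        hit = np.where(member_mask, weights / hit_total, 0.0)
    miss = np.where(member_mask, 0.0, 1.0 / (n - m))
    running = np.cumsum(hit - miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(
    ranked: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    weight: float = 1.0,
    nperm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-label permutation null.

    ``ranked`` is a (gene_id, score) frame in descending score order.  Sets
    are intersected with the ranked genes and filtered to
    [min_size, max_size].  For each surviving set the enrichment score (ES)
    is normalized by the mean |null ES| of matching sign (NES); nominal p is
    the matching-sign permutation tail, and FDR q follows the standard
    positive/negative pool-ratio construction on normalized scores.
    """
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    surviving: dict[str, np.ndarray] = {}
    for name in sorted(sets):
        pos = np.array(sorted(gene_pos[g] for g in set(sets[name]) if g in gene_pos), dtype=int)
        if min_size <= len(pos) <= max_size and len(pos) < n:
            mask = np.zeros(n, dtype=bool)
            mask[pos] = True
            surviving[name] = mask
    if not surviving:
        raise ValueError("no gene set survives the size filter")

    rng = np.random.default_rng(seed)
    sizes = sorted({int(m.sum()) for m in surviving.values()})
    null_by_size: dict[int, np.ndarray] = {}
    for size in sizes:
        null = np.empty(nperm)
        for b in range(nperm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=size, replace=False)] = True
            null[b] = enrichment_score(scores, mask, weight)
        null_by_size[size] = null

    rows = []
    all_nes_null: list[np.ndarray] = []
    for name, mask in surviving.items():
        size = int(mask.sum())
        es = enrichment_score(scores, mask, weight)
        null = null_by_size[size]
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        if es >= 0:
            nes = es / pos_mean if pos_mean and np.isfinite(pos_mean) else np.nan
            matching = null[null >= 0]
            p = (1 + (matching >= es).sum()) / (1 + len(matching)) if len(matching) else 1.0
        else:
            nes = -abs(es) / neg_mean if neg_mean and np.isfinite(neg_mean) else np.nan
            matching = null[null < 0]
            p = (1 + (matching <= es).sum()) / (1 + len(matching)) if len(matching) else 1.0
        nes_null = np.where(
            null >= 0,
            null / (pos_mean if pos_mean and np.isfinite(pos_mean) else np.inf),
            null / (neg_mean if neg_mean and np.isfinite(neg_mean) else np.inf),
        )
        all_nes_null.append(nes_null)
        rows.append({"set": name, "size": size, "es": es, "nes": nes, "p_nominal": float(p)})

    pooled_null = np.concatenate(all_nes_null)
    obs_nes = np.array([r["nes"] for r in rows])
    qvals = []
    for r in rows:
        nes = r["nes"]
        if not np.isfinite(nes):
            qvals.append(np.nan)
            continue
        if nes >= 0:
            null_frac = np.mean(pooled_null >= nes)
            obs_frac = np.mean(obs_nes[np.isfinite(obs_nes)] >= nes)
        else:
            null_frac = np.mean(pooled_null <= nes)
            obs_frac = np.mean(obs_nes[np.isfinite(obs_nes)] <= nes)
        q = null_frac / obs_frac if obs_frac > 0 else np.nan
        qvals.append(min(float(q), 1.0) if np.isfinite(q) else np.nan)
    out = pd.DataFrame(rows)
    out["fdr_q"] = qvals
    return out.sort_values("nes", ascending=False).reset_index(drop=True)


def write_ranked(ranked: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    ranked.to_csv(path, sep="\t", header=False, index=False)
    return path


def read_ranked(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"])
    return df.sort_values(["score", "gene_id"], ascending=[False, True]).reset_index(drop=True)
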