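"""Nearest-gene mapping, gene scoring and pre-ranked GSEA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from peakdiff.enrichment import (
    TssTable,
    enrichment_score,
    gene_scores,
    gsea_preranked,
    nearest_gene,
    read_gmt,
    read_ranked,
    write_ranked,
)
from peakdiff.intervals import GenomicInterval, PeakSet


def tss_table(rows):
    return TssTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]))


def make_peaks(spans, chrom="chr1"):
    return PeakSet([GenomicInterval(chrom, s, e, f"p{i}") for i, (s, e) in enumerate(spans)])


class TestNearestGene:
    def test_picks_nearer_tss_with_signed_distance(self):
        peaks = make_peaks([(400, 600)])  # midpoint 500
        tss = tss_table([("gA", "chr1", 400, "+"), ("gB", "chr1", 2000, "+")])
        out = nearest_gene(peaks, tss)
        assert out.loc[0, "gene_id"] == "gA"
        assert out.loc[0, "distance"] == 100.0

    def test_minus_strand_flips_sign(self):
        peaks = make_peaks([(400, 600)])
        tss = tss_table([("gA", "chr1", 400, "-")])
        out = nearest_gene(peaks, tss)
        assert out.loc[0, "distance"] == -100.0

    def test_distance_cutoff_unassigns(self):
        peaks = make_peaks([(0, 100)])
        tss = tss_table([("gA", "chr1", 150_000, "+")])
        out = nearest_gene(peaks, tss, max_distance=100_000)
        assert out.loc[0, "gene_id"] is None

    def test_missing_chromosome_warns(self):
        peaks = make_peaks([(0, 100)], chrom="chrX")
        tss = tss_table([("gA", "chr1", 0, "+")])
        with pytest.warns(UserWarning, match="chrX"):
            out = nearest_gene(peaks, tss)
        assert out.loc[0, "gene_id"] is None

    def test_tie_breaks_by_gene_id(self):
        peaks = make_peaks([(450, 550)])  # midpoint 500
        tss = tss_table([("gB", "chr1", 400, "+"), ("gA", "chr1", 600, "+")])
        assert nearest_gene(peaks, tss).loc[0, "gene_id"] == "gA"

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        spans = sorted({int(s) * 100 for s in rng.integers(0, 9000, size=300)})
        peaks = make_peaks([(s, s + 50) for s in spans])
        genes = [
            (f"g{i:02d}", "chr1", int(t), rng.choice(["+", "-"]))
            for i, t in enumerate(rng.integers(0, 900_000, size=50))
        ]
        tss = tss_table(genes)
        out = nearest_gene(peaks, tss, max_distance=100_000)
        for i, pk in enumerate(peaks):
            mid = pk.midpoint
            best = min(genes, key=lambda g: (abs(g[2] - mid), g[0]))
            if abs(best[2] - mid) > 100_000:
                assert out.loc[i, "gene_id"] is None
            else:
                assert out.loc[i, "gene_id"] == best[0]
                expect = mid - best[2] if best[3] == "+" else best[2] - mid
                assert out.loc[i, "distance"] == float(expect)


class TestGeneScores:
    def test_max_abs_wald_rule(self):
        assign = pd.DataFrame({"gene_id": ["g1", "g1"], "distance": [0.0, 0.0]})
        scores = gene_scores(np.array([3.0, -5.0]), assign)
        assert scores.loc[0, "score"] == -5.0

    def test_single_peak_genes_map_identically(self):
        assign = pd.DataFrame({"gene_id": ["g1", "g2"], "distance": [0.0, 0.0]})
        scores = gene_scores(np.array([2.0, 4.0]), assign)
        assert dict(zip(scores["gene_id"], scores["score"])) == {"g1": 2.0, "g2": 4.0}

    def test_matches_per_gene_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in rng.integers(0, 20, size=200)]
        wald = rng.normal(0, 3, size=200)
        assign = pd.DataFrame({"gene_id": genes, "distance": np.zeros(200)})
        scores = gene_scores(wald, assign).set_index("gene_id")["score"]
        for g in set(genes):
            vals = wald[np.array(genes) == g]
            assert scores[g] == vals[np.argmax(np.abs(vals))]

    def test_output_sorted_descending(self):
        rng = np.random.default_rng(2)
        assign = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(30)], "distance": np.zeros(30)}
        )
        scores = gene_scores(rng.normal(size=30), assign)
        assert np.all(np.diff(scores["score"]) <= 0)


class TestEnrichmentScore:
    def test_top_gene_singleton_set(self):
        scores = np.array([3.0, 2.0, 1.0, 0.1])
        mask = np.array([True, False, False, False])
        assert enrichment_score(scores, mask) == pytest.approx(1.0)

    def test_exhaustive_three_gene_sets_match_oracle(self):
        """ES for all 120 possible 3-gene sets equals a brute-force running sum."""
        rng = np.random.default_rng(3)
        scores = np.sort(rng.normal(0, 2, size=10))[::-1]
        for combo in itertools.combinations(range(10), 3):
            mask = np.zeros(10, dtype=bool)
            mask[list(combo)] = True
            run, best = 0.0, 0.0
            denom = np.abs(scores[mask]).sum()
            for i in range(10):
                run += abs(scores[i]) / denom if mask[i] else -1.0 / 7
                if abs(run) > abs(best):
                    best = run
            assert enrichment_score(scores, mask) == pytest.approx(best, abs=1e-12)

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(4)
        scores = np.sort(rng.normal(size=50))[::-1]
        mask = np.zeros(50, dtype=bool)
        mask[rng.choice(50, 8, replace=False)] = True
        es = enrichment_score(scores, mask)
        es_rev = enrichment_score(-scores[::-1], mask[::-1])
        assert es_rev == pytest.approx(-es, abs=1e-12)


class TestGseaPreranked:
    def ranked(self, rng, n=200):
        scores = np.sort(rng.normal(0, 2, size=n))[::-1]
        return pd.DataFrame({"gene_id": [f"g{i:03d}" for i in range(n)], "score": scores})

    def test_planted_top_decile_set_is_enriched(self):
        rng = np.random.default_rng(5)
        ranked = self.ranked(rng)
        planted = list(ranked["gene_id"].iloc[rng.choice(20, 20, replace=False)])
        sets = {"planted": planted,
                "random": list(rng.choice(ranked["gene_id"], 20, replace=False))}
        res = gsea_preranked(ranked, sets, nperm=1000, seed=9)
        row = res.set_index("set").loc["planted"]
        assert row["nes"] > 0 and row["fdr_q"] < 0.05

    def test_whole_list_set_excluded_by_filter(self):
        rng = np.random.default_rng(6)
        ranked = self.ranked(rng, n=50)
        sets = {"all": list(ranked["gene_id"]), "ok": list(ranked["gene_id"][:10])}
        res = gsea_preranked(ranked, sets, nperm=50, seed=0)
        assert list(res["set"]) == ["ok"]

    def test_reproducible_and_order_invariant(self):
        rng = np.random.default_rng(7)
        ranked = self.ranked(rng, n=100)
        s1 = {"a": list(ranked["gene_id"][:10]), "b": list(ranked["gene_id"][40:55])}
        s2 = dict(reversed(list(s1.items())))
        r1 = gsea_preranked(ranked, s1, nperm=200, seed=3)
        r2 = gsea_preranked(ranked, s2, nperm=200, seed=3)
        pd.testing.assert_frame_equal(
            r1.sort_values("set").reset_index(drop=True),
            r2.sort_values("set").reset_index(drop=True),
        )

    def test_nes_sign_matches_es_sign(self):
        rng = np.random.default_rng(8)
        ranked = self.ranked(rng, n=100)
        sets = {"top": list(ranked["gene_id"][:8]), "bottom": list(ranked["gene_id"][-8:])}
        res = gsea_preranked(ranked, sets, nperm=200, seed=1)
        assert np.all(np.sign(res["nes"]) == np.sign(res["es"]))
        assert res.set_index("set").loc["bottom", "es"] < 0


class TestIo:
    def test_gmt_round_trip_fields(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\t-\tg9\n")
        sets = read_gmt(p)
        assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g9"]}

    def test_ranked_list_round_trip(self, tmp_path):
        df = pd.DataFrame({"gene_id": ["a", "b", "c"], "score": [3.0, 1.0, -2.0]})
        path = write_ranked(df, tmp_path / "r.rnk")
        back = read_ranked(path)
        pd.testing.assert_frame_equal(back, df)
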