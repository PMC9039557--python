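"""Fragment filtering, midpoint counting, FRiP and RPKM."""

import numpy as np
import pytest

from peakdiff.counting import (
    AlignmentRecord,
    CountMatrix,
    count_reads,
    frip,
    library_size,
    rpkm,
)
from peakdiff.intervals import GenomicInterval, PeakSet


def rec(chrom="chr1", start=100, end=150, mapq=30, **kw):
    return AlignmentRecord(chrom=chrom, start=start, end=end, mapq=mapq, **kw)


def random_records(rng, n, chrom_len=10_000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, chrom_len - 60))
        out.append(
            AlignmentRecord(
                chrom="chr1",
                start=s,
                end=s + 50,
                mapq=int(rng.integers(0, 60)),
                unmapped=bool(rng.random() < 0.05),
                secondary=bool(rng.random() < 0.1),
                supplementary=bool(rng.random() < 0.05),
                duplicate=bool(rng.random() < 0.1),
            )
        )
    out.sort(key=lambda r: r.start)
    return out


class TestLibrarySize:
    def test_filters_secondary_and_unmapped(self):
        recs = [rec(), rec(), rec(), rec(secondary=True), rec(unmapped=True)]
        assert library_size(recs) == 3

    def test_proper_pairs_count_as_fragments(self):
        pair_kw = dict(paired=True, proper_pair=True)
        recs = [
            rec(start=100, end=150, first_in_pair=True, template_length=200, **pair_kw),
            rec(start=250, end=300, template_length=-200, **pair_kw),
            rec(start=400, end=450, first_in_pair=True, template_length=180, **pair_kw),
            rec(start=530, end=580, template_length=-180, **pair_kw),
        ]
        assert library_size(recs) == 2

    def test_mapq_threshold_is_configurable(self):
        recs = [rec(mapq=10), rec(mapq=25)]
        assert library_size(recs, min_mapq=5) == 2
        assert library_size(recs, min_mapq=20) == 1

    def test_empty_library_is_an_error(self):
        with pytest.raises(ValueError, match="empty library"):
            library_size([rec(unmapped=True)])

    def test_matches_record_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        recs = random_records(rng, 1000)
        oracle = sum(
            1
            for r in recs
            if not (r.unmapped or r.secondary or r.supplementary or r.duplicate)
            and r.mapq >= 20
        )
        assert library_size(recs) == oracle


class TestCountReads:
    def make_peaks(self, spans):
        return PeakSet([GenomicInterval("chr1", s, e, f"p{i}") for i, (s, e) in enumerate(spans)])

    def test_midpoint_inside_peak_counts(self):
        peaks = self.make_peaks([(0, 130)])
        counts, total, lib = count_reads([rec(start=100, end=150)], peaks)
        assert counts.tolist() == [1] and total == 1 and lib == 1

    def test_midpoint_outside_peak_does_not_count(self):
        peaks = self.make_peaks([(0, 120)])
        counts, total, _ = count_reads([rec(start=100, end=150)], peaks)
        assert counts.tolist() == [0] and total == 0

    def test_unsorted_stream_is_an_error(self):
        peaks = self.make_peaks([(0, 100)])
        with pytest.raises(ValueError, match="sorted"):
            count_reads([rec(start=500), rec(start=100)], peaks)

    def test_mixed_paired_and_single_end_is_an_error(self):
        peaks = self.make_peaks([(0, 1000)])
        pair = rec(start=200, paired=True, proper_pair=True, first_in_pair=True,
                   template_length=100)
        with pytest.raises(ValueError, match="mixed"):
            count_reads([rec(start=100), pair], peaks)

    def test_matches_all_pairs_oracle(self):
        """2000 simulated reads over 50 peaks equal brute-force enumeration."""
        rng = np.random.default_rng(7)
        starts = np.arange(50) * 400 + 17
        peaks = self.make_peaks([(int(s), int(s + rng.integers(50, 300))) for s in starts])
        recs = random_records(rng, 2000, chrom_len=21_000)
        counts, total, lib = count_reads(recs, peaks)
        oracle = np.zeros(50, dtype=int)
        n_assigned = 0
        for r in recs:
            if (r.unmapped or r.secondary or r.supplementary or r.duplicate
                    or r.mapq < 20):
                continue
            mid = (r.start + r.end) // 2
            hits = [i for i, pk in enumerate(peaks) if pk.start <= mid < pk.end]
            assert len(hits) <= 1  # disjoint universe: no double counting
            for i in hits:
                oracle[i] += 1
                n_assigned += 1
        assert counts.tolist() == oracle.tolist()
        assert total == n_assigned == counts.sum()

    def test_invariant_to_stream_chunking(self):
        rng = np.random.default_rng(9)
        peaks = self.make_peaks([(100, 400), (600, 900)])
        recs = random_records(rng, 500, chrom_len=1000)
        whole, total, lib = count_reads(recs, peaks)
        part = np.zeros_like(whole)
        lib2 = 0
        for chunk in (recs[:100], recs[100:350], recs[350:]):
            if not chunk:
                continue
            c, _, l = count_reads(chunk, peaks, check_sorted=False)
            part += c
            lib2 += l
        assert whole.tolist() == part.tolist() and lib == lib2

    def test_paired_fragment_midpoint_from_template_span(self):
        # fragment spans [100, 300): midpoint 200 lands in second peak only
        peaks = self.make_peaks([(0, 150), (160, 250)])
        r1 = rec(start=100, end=150, paired=True, proper_pair=True,
                 first_in_pair=True, template_length=200)
        r2 = rec(start=250, end=300, paired=True, proper_pair=True,
                 template_length=-200)
        counts, total, lib = count_reads([r1, r2], peaks)
        assert counts.tolist() == [0, 1] and lib == 1


class TestRpkmFrip:
    def make_cm(self, counts, lengths, libs):
        peaks = PeakSet(
            [GenomicInterval("chr1", i * 10_000, i * 10_000 + ln, f"p{i}")
             for i, ln in enumerate(lengths)]
        )
        counts = np.asarray(counts)
        return CountMatrix(
            peaks=peaks,
            samples=[f"s{j}" for j in range(counts.shape[1])],
            counts=counts,
            library_sizes=np.asarray(libs),
        )

    def test_rpkm_formula(self):
        cm = self.make_cm([[100]], [500], [10_000_000])
        assert rpkm(cm)[0, 0] == pytest.approx(20.0)

    def test_zero_count_gives_zero(self):
        cm = self.make_cm([[0]], [500], [10_000_000])
        assert rpkm(cm)[0, 0] == 0.0

    def test_doubling_library_halves_column(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 100, size=(20, 2))
        lengths = rng.integers(100, 1000, size=20)
        cm1 = self.make_cm(counts, lengths, [1_000_000, 1_000_000])
        cm2 = self.make_cm(counts, lengths, [1_000_000, 2_000_000])
        np.testing.assert_allclose(rpkm(cm2)[:, 1] * 2, rpkm(cm1)[:, 1])

    def test_frip_definition_and_bounds(self):
        cm = self.make_cm([[50_000], [50_000]], [300, 300], [1_000_000])
        assert frip(cm)[0] == pytest.approx(0.10)
        cm_all = self.make_cm([[7]], [300], [7])
        assert frip(cm_all)[0] == 1.0

    def test_column_sums_match_frip_numerator(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 50, size=(30, 3))
        cm = self.make_cm(counts, rng.integers(100, 500, size=30), [10_000] * 3)
        np.testing.assert_array_equal(cm.in_peak_totals, counts.sum(axis=0))
        np.testing.assert_allclose(frip(cm), counts.sum(axis=0) / 10_000)
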