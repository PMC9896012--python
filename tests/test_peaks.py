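import numpy as np
import pandas as pd
import pytest

from tfcrosstalk.intervals import GenomicInterval
from tfcrosstalk.io import CoverageTrack
from tfcrosstalk.peaks import (
    BindingSite,
    Peak,
    VennCounts,
    annotate_tss,
    background_threshold,
    call_peaks_enrichment,
    call_peaks_shape,
    canonical_sites,
    classify_venn,
    consensus,
    exclude_blacklist,
    filter_peaks,
    pairwise_union,
    reproducible,
)


def track(values, bin_width=1, library_size=None):
    arr = np.asarray(values, dtype=float)
    return CoverageTrack({"chr1": arr}, bin_width=bin_width,
                         library_size=library_size or max(float(arr.sum()), 1.0))


def bump(length, centre, height, width, base=1.0):
    x = np.arange(length, dtype=float)
    return base + height * np.clip(1 - np.abs(x - centre) / width, 0, None)


def peak(start, end, summit=None, count=10.0, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), summit if summit is not None else start, 0.0, count)


class TestEnrichmentCaller:
    def test_flat_signal_no_peaks(self):
        s = track(np.ones(2000))
        c = track(np.ones(2000))
        assert call_peaks_enrichment(s, c) == []

    def test_single_bump_summit_at_apex(self):
        sig = bump(4000, 2000, 20.0, 200)
        s, c = track(sig), track(np.ones(4000), library_size=float(sig.sum()))
        peaks = call_peaks_enrichment(s, c, min_fold=4, min_len=100)
        assert len(peaks) == 1
        assert abs(peaks[0].summit - 2000) <= 1
        assert peaks[0].interval.start <= 2000 < peaks[0].interval.end

    def test_two_bumps_not_merged(self):
        sig = bump(4000, 1000, 20.0, 150) + bump(4000, 2600, 20.0, 150) - 1.0
        s, c = track(sig), track(np.ones(4000), library_size=float(sig.sum()))
        peaks = call_peaks_enrichment(s, c, min_fold=4, min_len=100)
        assert len(peaks) == 2

    def test_mismatched_chromosomes_error(self):
        s = CoverageTrack({"chr1": np.ones(10)})
        c = CoverageTrack({"chr2": np.ones(10)})
        with pytest.raises(ValueError):
            call_peaks_enrichment(s, c)


class TestShapeCaller:
    def test_single_bump_overlaps_caller_a(self):
        sig = bump(4000, 2000, 20.0, 200)
        s = track(sig)
        c = track(np.ones(4000), library_size=float(sig.sum()))
        pa = call_peaks_enrichment(s, c, min_fold=4, min_len=100)
        pb = call_peaks_shape(s, bandwidth=50, prominence=5.0)
        assert len(pb) == 1
        assert pb[0].interval.overlaps(pa[0].interval)

    def test_sawtooth_below_prominence_no_peaks(self):
        sig = 1.0 + np.tile([0.0, 1.0], 2000)
        assert call_peaks_shape(track(sig), bandwidth=10, prominence=5.0) == []

    def test_plateau_summit_at_midpoint(self):
        sig = np.ones(2000)
        sig[900:1101] = 30.0
        peaks = call_peaks_shape(track(sig), bandwidth=20, prominence=5.0)
        assert len(peaks) == 1
        assert abs(peaks[0].summit - 1000) <= 1

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            call_peaks_shape(track(np.ones(100)), bandwidth=0)


class TestSetLogic:
    def test_one_bp_overlap_kept(self):
        a, b = [peak(100, 200)], [peak(199, 300)]
        assert len(consensus(a, b)) == 1

    def test_half_open_touching_dropped(self):
        a, b = [peak(100, 200)], [peak(200, 300)]
        assert consensus(a, b) == []

    def test_consensus_matches_all_pairs_oracle(self, rng):
        def rand_peaks(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 5000))
                out.append(peak(s, s + int(rng.integers(1, 200)), chrom=f"chr{rng.integers(1, 3)}"))
            return out

        for _ in range(20):
            a, b = rand_peaks(40), rand_peaks(40)
            expected = [p for p in a if any(p.interval.overlaps(q.interval) for q in b)]
            got = consensus(a, b)
            assert [id(p) for p in got] == [id(p) for p in expected]
            assert all(p in a for p in got)  # consensus(A, B) subset of A

    def test_blacklist_removes_overlapping(self, rng):
        pk = [peak(0, 100), peak(500, 600), peak(1000, 1100)]
        bl = [GenomicInterval("chr1", 599, 700)]
        kept = exclude_blacklist(pk, bl)
        assert [p.interval.start for p in kept] == [0, 1000]

    def test_reproducible_mirrors_consensus(self):
        r1, r2 = [peak(10, 50), peak(100, 150)], [peak(49, 90)]
        assert [p.interval.start for p in reproducible(r1, r2)] == [10]


class TestBackgroundFilter:
    def test_quantile_matches_sorted_array_oracle(self, rng):
        counts = rng.gamma(2.0, 50.0, size=20_000)
        for q in (0.5, 0.9, 0.9999):
            expected = np.quantile(np.sort(counts), q, method="linear")
            assert background_threshold(counts, q) == pytest.approx(expected)

    def test_all_equal_counts(self):
        assert background_threshold(np.full(100, 7.0), 0.9999) == 7.0

    def test_median_small_set(self):
        assert background_threshold(np.array([1.0, 2.0, 3.0]), 0.5) == 2.0

    def test_small_set_warns_at_extreme_quantile(self):
        with pytest.warns(UserWarning, match="recommended"):
            background_threshold(np.array([1.0, 2.0, 3.0]), 0.9999)

    def test_large_grid_quantile(self):
        counts = np.arange(1.0, 10_001.0)
        thr = background_threshold(counts, 0.9999)
        assert thr == pytest.approx(9999.0001, abs=1e-6)

    def test_empty_set_error(self):
        with pytest.raises(ValueError):
            background_threshold(np.array([]), 0.9999)

    def test_strictly_greater_filter(self):
        pk = [peak(0, 10, count=5), peak(20, 30, count=10), peak(40, 50, count=11)]
        assert len(filter_peaks(pk, 10)) == 1

    def test_zero_threshold_keeps_positive(self):
        pk = [peak(0, 10, count=0), peak(20, 30, count=0.5)]
        assert len(filter_peaks(pk, 0)) == 1

    def test_filter_matches_brute_force(self, rng):
        pk = [peak(i * 20, i * 20 + 10, count=float(c)) for i, c in enumerate(rng.integers(0, 100, 50))]
        thr = 42.0
        assert [p.total_count for p in filter_peaks(pk, thr)] == [
            p.total_count for p in pk if p.total_count > thr
        ]

    def test_raising_q_never_adds_peaks(self, rng):
        counts = rng.gamma(2.0, 30.0, size=5_000)
        pk = [peak(i * 20, i * 20 + 10, count=float(c)) for i, c in enumerate(rng.gamma(2.0, 30.0, 200))]
        survivors = [
            len(filter_peaks(pk, background_threshold(counts, q)))
            for q in (0.5, 0.9, 0.99, 0.999, 0.9999)
        ]
        assert survivors == sorted(survivors, reverse=True)


class TestCanonicalSites:
    def test_no_arnt_overlap_excluded(self):
        sites = canonical_sites([peak(0, 100)], [peak(50, 150)], [peak(500, 600)], [peak(550, 650)])
        assert sites == []

    def test_four_way_overlap_included(self):
        sites = canonical_sites(
            [peak(0, 100, summit=50)], [peak(50, 150)], [peak(80, 160)], [peak(90, 170)],
            factor="AHR",
        )
        assert len(sites) == 1
        assert sites[0].interval.start == 0  # factor rep1 coordinates
        assert sites[0].summits == {"AHR": 50}

    def test_matches_brute_force_intersection(self, rng):
        def rand_peaks(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 3000))
                out.append(peak(s, s + int(rng.integers(20, 150))))
            return out

        f1, f2, a1, a2 = (rand_peaks(30) for _ in range(4))
        got = canonical_sites(f1, f2, a1, a2)
        repro_f = [p for p in f1 if any(p.interval.overlaps(q.interval) for q in f2)]
        repro_a = [p for p in a1 if any(p.interval.overlaps(q.interval) for q in a2)]
        expected = [
            p for p in repro_f if any(p.interval.overlaps(q.interval) for q in repro_a)
        ]
        assert [s.interval.start for s in got] == [p.interval.start for p in expected]


def site(start, end, cls="", chrom="chr1", summits=None):
    return BindingSite(GenomicInterval(chrom, start, end), site_class=cls, summits=summits or {})


class TestVenn:
    def test_disjoint_toy_sets(self):
        merged, venn = classify_venn(
            {"A": [site(0, 10)], "B": [site(100, 110)], "C": [site(200, 210)]}
        )
        assert venn.union() == 3
        assert venn.multi_factor() == 0
        assert all(len(c) == 1 for c in venn.region_counts)

    def test_counts_match_brute_force(self, rng):
        factors = {}
        for name in ("AHR", "HIF1", "HIF2"):
            starts = rng.integers(0, 4000, 40)
            factors[name] = [site(int(s), int(s) + int(rng.integers(10, 120))) for s in starts]
        merged, venn = classify_venn(factors)
        # brute force on the merged universe
        from tfcrosstalk.intervals import merge_intervals

        universe = merge_intervals([s.interval for ss in factors.values() for s in ss])
        expected: dict[frozenset, int] = {}
        for block in universe:
            combo = frozenset(
                f for f, ss in factors.items() if any(block.overlaps(s.interval) for s in ss)
            )
            if combo:
                expected[combo] = expected.get(combo, 0) + 1
        assert venn.region_counts == expected
        # inclusion-exclusion identity
        tot = {f: venn.total(f) for f in factors}
        pair = {
            (a, b): sum(n for c, n in venn.region_counts.items() if a in c and b in c)
            for a in factors for b in factors if a < b
        }
        triple = venn.region_counts.get(frozenset(factors), 0)
        ie = sum(tot.values()) - sum(pair.values()) + triple
        assert ie == venn.union()

    def test_printed_count_union_arithmetic(self):
        assert pairwise_union(828, 401, 246) == 983

    def test_overlap_percentage_rounding(self):
        vc = VennCounts({frozenset({"A"}): 1712, frozenset({"A", "B"}): 221})
        assert vc.union() == 1933
        assert vc.overlap_percentage() == 11
        vc2 = VennCounts({frozenset({"A"}): 955, frozenset({"A", "B"}): 221})
        assert vc2.total("A") == 1176
        assert vc2.overlap_percentage("A") == 19


class TestTssAnnotation:
    def tss_table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "strand"])

    def test_plus_strand_upstream_negative(self):
        s = site(900, 1100, summits={"AHR": 1000})
        annotate_tss([s], self.tss_table([("g1", "chr1", 1500, "+")]))
        assert s.tss_distance == -500

    def test_minus_strand_sign(self):
        s = site(900, 1100, summits={"AHR": 1000})
        annotate_tss([s], self.tss_table([("g1", "chr1", 500, "-")]))
        assert s.tss_distance == -500

    def test_nearest_matches_brute_force(self, rng):
        tss = self.tss_table(
            [(f"g{i}", "chr1", int(p), "+" if rng.random() < 0.5 else "-")
             for i, p in enumerate(sorted(rng.integers(0, 100_000, 60)))]
        )
        sites = [site(int(p), int(p) + 200, summits={"A": int(p) + 100})
                 for p in rng.integers(0, 99_000, 40)]
        annotate_tss(sites, tss)
        for s in sites:
            summit = s.summits["A"]
            dists = (tss["pos"] - summit).abs()
            assert abs(s.tss_distance) == dists.min()
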