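"""Promoter windows, Fisher overlap, quintiles, and metagene profiles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact

from ripitseq.chip import (
    Peak,
    PeakSet,
    SignalTrack,
    chip_bound_genes,
    classify_genes,
    fisher_overlap,
    fisher_pvalue,
    metagene_profile,
    promoter_interval,
    promoter_signal,
    read_bedgraph,
    read_peaks_bed,
    top_quintile_promoters,
    write_bedgraph,
    write_peaks_bed,
)
from conftest import make_gene


class TestPromoterWindows:
    def test_plus_strand_window(self):
        g = make_gene(strand="+", tss=10_000, exons=((10_000, 12_000),))
        p = promoter_interval(g)
        assert (p.start, p.end) == (8000, 11_000)
        assert p.end - p.start == 3000

    def test_minus_strand_window_is_mirrored(self):
        g = make_gene(strand="-", tss=10_000, exons=((8000, 10_000),))
        p = promoter_interval(g)
        assert (p.start, p.end) == (9000, 12_000)

    def test_clipped_at_chromosome_start(self):
        g = make_gene(strand="+", tss=500, exons=((500, 2000),))
        p = promoter_interval(g)
        assert (p.start, p.end) == (0, 1500)

    def test_contains_tss(self):
        for strand in "+-":
            g = make_gene(strand=strand, tss=50_000, exons=((48_000, 52_000),))
            p = promoter_interval(g)
            assert p.start <= g.tss < p.end


class TestChipBoundGenes:
    def test_overlap_by_one_bp_counts(self):
        g = make_gene(strand="+", tss=10_000, exons=((10_000, 12_000),))
        assert chip_bound_genes([g], PeakSet([Peak("chr1", 8500, 8600)])) == {"g1"}
        assert chip_bound_genes([g], PeakSet([Peak("chr1", 10_999, 11_500)])) == {"g1"}

    def test_half_open_adjacency_is_not_overlap(self):
        g = make_gene(strand="+", tss=10_000, exons=((10_000, 12_000),))
        # promoter is [8000, 11000); a peak ending at 8000 or starting at 11000 misses
        assert chip_bound_genes([g], PeakSet([Peak("chr1", 11_000, 11_100)])) == set()
        assert chip_bound_genes([g], PeakSet([Peak("chr1", 7000, 8000)])) == set()

    def test_empty_peak_set(self):
        assert chip_bound_genes([make_gene()], PeakSet([])) == set()

    def test_monotone_in_peaks(self):
        rng = np.random.default_rng(2)
        genes = [
            make_gene(f"g{i}", tss=int(t), exons=((int(t), int(t) + 500),))
            for i, t in enumerate(rng.integers(3000, 500_000, size=30))
        ]
        peaks = [
            Peak("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 500_000, size=40)
        ]
        bound_few = chip_bound_genes(genes, PeakSet(peaks[:10]))
        bound_all = chip_bound_genes(genes, PeakSet(peaks))
        assert bound_few <= bound_all


def oracle_fisher(k, K, n, N, alternative):
    """Exact enumeration with Fraction hypergeometric pmfs (independent path)."""
    lo, hi = max(0, K + n - N), min(K, n)
    den = math.comb(N, n)
    pmf = {j: Fraction(math.comb(K, j) * math.comb(N - K, n - j), den) for j in range(lo, hi + 1)}
    if alternative == "greater":
        return float(sum(p for j, p in pmf.items() if j >= k))
    return float(sum(p for p in pmf.values() if p <= pmf[k]))


class TestFisher:
    def test_worked_example(self):
        # table [[3,1],[1,3]] over a universe of 8
        assert fisher_pvalue(3, 4, 4, 8, "greater") == pytest.approx(17 / 70, abs=1e-12)
        assert fisher_pvalue(3, 4, 4, 8, "two-sided") == pytest.approx(34 / 70, abs=1e-12)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            N = int(rng.integers(1, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, K + n - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            table = [[k, K - k], [n - k, N - K - n + k]]
            for alt, scipy_alt in (("greater", "greater"), ("two-sided", "two-sided")):
                ours = fisher_pvalue(k, K, n, N, alt)
                ref = fisher_exact(table, alternative=scipy_alt)[1]
                assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_exhaustive_small_universes(self):
        for N in range(1, 25):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo, hi = max(0, K + n - N), min(K, n)
                    for k in range(lo, hi + 1):
                        for alt in ("greater", "two-sided"):
                            assert fisher_pvalue(k, K, n, N, alt) == pytest.approx(
                                oracle_fisher(k, K, n, N, alt), abs=1e-10
                            )

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError):
            fisher_pvalue(5, 4, 4, 8)


class TestFisherOverlap:
    def test_worked_sets(self):
        universe = {f"g{i}" for i in range(8)}
        a = {"g0", "g1", "g2", "g3"}
        b = {"g0", "g1", "g2", "g4"}
        res = fisher_overlap(universe, a, b, "two-sided")
        assert res.table == [[3, 1], [1, 3]]
        assert res.p_value == pytest.approx(0.48571, abs=5e-6)
        assert res.odds_ratio == pytest.approx(9.0)

    def test_degenerate_full_overlap(self):
        u = {"a", "b", "c"}
        res = fisher_overlap(u, u, u)
        assert res.p_value == pytest.approx(1.0)
        assert math.isinf(res.odds_ratio) or math.isnan(res.odds_ratio)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_overlap(set(), set(), set())

    def test_odds_ratio_near_one_under_independence(self):
        rng = np.random.default_rng(21)
        logs = []
        universe = [f"g{i}" for i in range(400)]
        for _ in range(100):
            a = {g for g in universe if rng.random() < 0.5}
            b = {g for g in universe if rng.random() < 0.5}
            res = fisher_overlap(universe, a, b)
            if 0 < res.odds_ratio < math.inf:
                logs.append(math.log(res.odds_ratio))
        assert abs(np.mean(logs)) < 0.1

    def test_class_counts_partition_universe(self, small_sim):
        genes = small_sim["genes"]
        universe = {g.gene_id for g in genes}
        chip = set(small_sim["truth"].peaked)
        rip = set(small_sim["truth"].binders)
        res = fisher_overlap(universe, chip, rip)
        counts = res.class_counts()
        assert sum(counts.values()) == len(universe)
        assert counts["both"] + counts["chip_only"] == len(chip)
        assert counts["both"] + counts["rip_only"] == len(rip)
        assert res.n_both <= min(res.n_chip, res.n_rip)


class TestClassify:
    def test_exhaustive_hand_classification(self):
        classes = classify_genes(
            {"g1", "g2", "g3", "g4"}, {"g1", "g2"}, {"g2", "g3"}
        )
        assert classes == {
            "g1": "chip_only",
            "g2": "both",
            "g3": "rip_only",
            "g4": "neither",
        }

    def test_disjoint_sets(self):
        classes = classify_genes({"a", "b"}, {"a"}, {"b"})
        assert sum(1 for v in classes.values() if v == "both") == 0


class TestTopQuintile:
    def test_distinct_signals_top_20_percent(self):
        signal = {f"g{i}": float(i) for i in range(10)}
        assert top_quintile_promoters(signal) == {"g8", "g9"}

    def test_all_ties_resolved_by_gene_id(self, caplog):
        signal = {f"g{i}": 1.0 for i in range(10)}
        with caplog.at_level("WARNING"):
            top = top_quintile_promoters(signal)
        assert top == {"g0", "g1"}
        assert "tie" in caplog.text

    def test_singleton(self):
        assert top_quintile_promoters({"only": 0.0}) == {"only"}

    @pytest.mark.parametrize("n", [1, 4, 5, 6, 23, 100])
    def test_always_ceil_n_over_5(self, n):
        signal = {f"g{i:03d}": float(i % 7) for i in range(n)}
        assert len(top_quintile_promoters(signal)) == math.ceil(n / 5)


def constant_track(c=2.5, length=100_000):
    return SignalTrack({"chr1": [(0, length, c)]}, {"chr1": length})


class TestMetagene:
    def test_constant_coverage_gives_flat_profile(self):
        track = constant_track(2.5)
        genes = [
            make_gene("a", tss=20_000, exons=((20_000, 21_000),)),
            make_gene("b", strand="-", tss=60_000, exons=((59_000, 60_000),)),
        ]
        prof = metagene_profile(track, genes)
        assert np.allclose(prof.mean_signal, 2.5)
        assert prof.n_per_bin.tolist() == [2] * 100

    def test_strand_mirror_invariance(self):
        rng = np.random.default_rng(4)
        length = 60_000
        values = rng.uniform(0, 5, size=60)
        ivs = [(i * 1000, (i + 1) * 1000, float(v)) for i, v in enumerate(values)]
        track = SignalTrack({"chr1": ivs}, {"chr1": length})
        tss = 30_000
        plus = make_gene("p", strand="+", tss=tss, exons=((tss, tss + 500),))
        # mirrored track about the TSS, gene on the minus strand
        mirrored = [
            (2 * tss - e, 2 * tss - s, v) for s, e, v in ivs if 2 * tss - s > 0
        ]
        track_m = SignalTrack({"chr1": mirrored}, {"chr1": length})
        minus = make_gene("m", strand="-", tss=tss, exons=((tss - 500, tss),))
        prof_p = metagene_profile(track, [plus])
        prof_m = metagene_profile(track_m, [minus])
        assert np.allclose(prof_p.mean_signal, prof_m.mean_signal)

    def test_single_50bp_block_downstream_of_tss(self):
        tss = 50_000
        track = SignalTrack({"chr1": [(tss, tss + 50, 1.0)]}, {"chr1": 100_000})
        gene = make_gene("g", strand="+", tss=tss, exons=((tss, tss + 2000),))
        prof = metagene_profile(track, [gene], window=5000, n_bins=100)
        nonzero = np.flatnonzero(prof.mean_signal)
        assert nonzero.tolist() == [50]  # the first bin downstream of the TSS
        assert prof.mean_signal[50] == pytest.approx(0.5)

    def test_out_of_bounds_bins_are_missing(self):
        track = constant_track(1.0, length=6000)
        gene = make_gene("g", tss=1000, exons=((1000, 2000),))
        prof = metagene_profile(track, [gene], window=5000, n_bins=100)
        # window [-4000, 6000): first 40 bins fall below position 0
        assert prof.n_per_bin[:40].tolist() == [0] * 40
        assert np.all(np.isnan(prof.mean_signal[:40]))
        assert np.allclose(prof.mean_signal[40:], 1.0)

    def test_simulated_peaked_promoters_show_central_maximum(self, small_sim):
        genes = small_sim["genes"]
        track = small_sim["track"]
        peaked = set(small_sim["truth"].peaked)
        cfg = small_sim["config"]
        prof_peaked = metagene_profile(track, [g for g in genes if g.gene_id in peaked])
        prof_flat = metagene_profile(track, [g for g in genes if g.gene_id not in peaked])
        center = np.nanmax(prof_peaked.mean_signal[45:55])
        assert center > 5 * cfg.background
        # central bins should dominate the window edges
        assert center > 3 * np.nanmean(prof_peaked.mean_signal[:10])
        assert np.nanmean(prof_flat.mean_signal) < 2 * cfg.background


class TestSignalIO:
    def test_bedgraph_round_trip(self, tmp_path, small_sim):
        track = small_sim["track"]
        path = tmp_path / "sig.bedgraph"
        write_bedgraph(track, path)
        back = read_bedgraph(path, small_sim["config"].chrom_lengths())
        g = small_sim["genes"][0]
        a = track.window_bin_means(g.chrom, g.tss - 5000, g.tss + 5000, 100)
        b = back.window_bin_means(g.chrom, g.tss - 5000, g.tss + 5000, 100)
        assert np.allclose(a, b, equal_nan=True)

    def test_peaks_round_trip(self, tmp_path, small_sim):
        peaks = small_sim["peaks"]
        path = tmp_path / "peaks.bed"
        write_peaks_bed(peaks, path)
        back = read_peaks_bed(path)
        assert [(p.chrom, p.start, p.end) for p in back.peaks] == [
            (p.chrom, p.start, p.end) for p in peaks.peaks
        ]

    def test_promoter_signal_track_vs_peak_fallback(self, small_sim):
        genes = small_sim["genes"][:30]
        by_track = promoter_signal(genes, small_sim["track"])
        by_peaks = promoter_signal(genes, None, small_sim["peaks"])
        peaked = set(small_sim["truth"].peaked)
        for g in genes:
            if g.gene_id in peaked:
                assert by_track[g.gene_id] > small_sim["config"].background
                assert by_peaks[g.gene_id] > 0
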