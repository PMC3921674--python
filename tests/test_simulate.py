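"""Synthetic-data generator: determinism, round trips, parameter recovery."""

import numpy as np
import pytest

from ripitseq.annotation import assemble_transcriptome, read_bed12
from ripitseq.chip import chip_bound_genes, read_bedgraph, read_peaks_bed
from ripitseq.enrichment import call_all
from ripitseq.quantify import build_expression_matrix, read_counts_tsv
from ripitseq.simulate import (
    SimConfig,
    SimTruth,
    design_samples,
    simulate_annotation,
    simulate_chip,
    simulate_counts,
    simulate_dataset,
    write_dataset,
)


def small_config(seed=1, **kw):
    defaults = dict(
        n_genes=100, n_chroms=2, chrom_length=700_000, depth=6e4, seed=seed
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, binder_fraction=1.5)
        with pytest.raises(ValueError):
            SimConfig(seed=1, dispersion=-0.1)
        with pytest.raises(ValueError):
            SimConfig(seed=1, unassigned_fraction=1.0)

    def test_too_dense_genome_is_an_error(self):
        with pytest.raises(ValueError, match="cannot fit"):
            simulate_annotation(SimConfig(seed=1, n_genes=5000, chrom_length=100_000))


class TestDeterminism:
    def test_same_seed_same_dataset(self):
        a = simulate_dataset(small_config(seed=5))
        b = simulate_dataset(small_config(seed=5))
        assert a[1] == b[1]  # gene models
        assert np.array_equal(a[2].counts, b[2].counts)
        assert a[3].binders == b[3].binders
        assert [(p.chrom, p.start, p.end, p.score) for p in a[4].peaks] == [
            (p.chrom, p.start, p.end, p.score) for p in b[4].peaks
        ]

    def test_different_seeds_differ(self):
        a = simulate_dataset(small_config(seed=5))
        b = simulate_dataset(small_config(seed=6))
        assert not np.array_equal(a[2].counts, b[2].counts)

    def test_written_outputs_byte_identical(self, tmp_path):
        p1 = write_dataset(tmp_path / "a", small_config(seed=9))
        p2 = write_dataset(tmp_path / "b", small_config(seed=9))
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()


class TestAnnotationSim:
    def test_zero_genes(self):
        records, genes = simulate_annotation(small_config(n_genes=0))
        assert records == [] and genes == []

    def test_genes_do_not_overlap_and_sit_on_both_strands(self):
        cfg = SimConfig(seed=3, n_genes=1000, n_chroms=2, chrom_length=6_000_000)
        _, genes = simulate_annotation(cfg)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for members in by_chrom.values():
            members.sort(key=lambda g: g.start)
            for a, b in zip(members, members[1:]):
                assert a.end <= b.start
        n_plus = sum(g.strand == "+" for g in genes)
        # binomial(1000, 0.5): 4 sigma is ~63
        assert abs(n_plus - 500) < 65


class TestCountsSim:
    def test_design_layout(self):
        spec = design_samples()
        assert len(spec) == 8
        conds = [c for _, c, r, _ in spec if r == "pulldown"]
        assert conds == ["WT_rep1", "WT_rep2", "F266A", "vector"]

    def test_truth_binder_count(self):
        cfg = small_config(binder_fraction=0.1)
        _, genes = simulate_annotation(cfg)
        _, truth = simulate_counts(genes, cfg)
        assert len(truth.binders) == round(0.1 * len(genes))

    def test_library_sizes_cover_counts(self):
        cfg = small_config()
        _, genes = simulate_annotation(cfg)
        table, _ = simulate_counts(genes, cfg)
        colsums = table.counts.sum(axis=0)
        for s, tot in zip(table.samples, colsums):
            assert s.library_size >= tot

    def test_binder_effect_recovered_in_scores(self):
        """With a strong planted effect and deep sampling, the mean WT
        enrichment score of binders approaches the effect minus the
        compositional depletion of the pulldown library."""
        cfg = small_config(
            seed=11, depth=5e5, binder_effect=3.0, binder_fraction=0.05, dispersion=0.02
        )
        _, genes = simulate_annotation(cfg)
        table, truth = simulate_counts(genes, cfg)
        expr = build_expression_matrix(table, genes)
        _, frame = call_all(expr, table.samples)
        binders = sorted(truth.binders)
        wt_scores = frame.loc[binders, ["score_WT_rep1", "score_WT_rep2"]].to_numpy()
        n_binders = len(binders)
        shift = np.log2(1 + n_binders / len(genes) * (2**3 - 1))
        # pseudocount shrinks scores toward zero, so allow a generous band
        assert 3.0 - shift - 0.8 < wt_scores.mean() < 3.0 + 0.2

    def test_recovery_sensitivity_specificity(self):
        """Planted binders are recovered with high sensitivity/specificity
        across replicate simulations."""
        sens, spec = [], []
        for seed in range(20):
            cfg = small_config(seed=100 + seed, depth=3e5, n_genes=200,
                               chrom_length=1_200_000, binder_effect=3.0)
            _, genes = simulate_annotation(cfg)
            table, truth = simulate_counts(genes, cfg)
            expr = build_expression_matrix(table, genes)
            _, frame = call_all(expr, table.samples)
            called = set(frame.index[frame["enriched"]])
            binders = set(truth.binders)
            others = set(frame.index) - binders
            sens.append(len(called & binders) / len(binders))
            spec.append(len(others - called) / len(others))
        assert np.mean(sens) >= 0.9
        assert np.mean(spec) >= 0.9


class TestChipSim:
    def test_zero_peak_fraction(self):
        cfg = small_config(chip_peak_fraction=0.0)
        _, genes = simulate_annotation(cfg)
        table, truth = simulate_counts(genes, cfg)
        peaks, track = simulate_chip(genes, cfg, truth)
        assert len(peaks) == 0
        assert truth.peaked == []
        vals = track.window_bin_means("chr1", 0, 10_000, 10)
        assert np.allclose(vals, cfg.background)

    def test_all_promoters_peaked_closes_with_overlap_op(self):
        cfg = small_config(chip_peak_fraction=1.0)
        _, genes = simulate_annotation(cfg)
        table, truth = simulate_counts(genes, cfg)
        peaks, _ = simulate_chip(genes, cfg, truth)
        assert chip_bound_genes(genes, peaks) == {g.gene_id for g in genes}

    def test_binder_peak_fraction_enriches_both_class(self):
        cfg = small_config(
            seed=13, n_genes=400, chrom_length=2_500_000,
            binder_fraction=0.2, chip_peak_fraction=0.2, binder_peak_fraction=0.9,
        )
        _, genes = simulate_annotation(cfg)
        table, truth = simulate_counts(genes, cfg)
        _, _ = simulate_chip(genes, cfg, truth)
        binders, peaked = set(truth.binders), set(truth.peaked)
        frac_binders_peaked = len(binders & peaked) / len(binders)
        frac_others_peaked = len(peaked - binders) / (len(genes) - len(binders))
        assert frac_binders_peaked > 0.75
        assert frac_others_peaked < 0.35


def test_round_trip_through_standard_readers(tmp_path):
    """Every written artifact reloads losslessly through the package readers."""
    cfg = small_config(seed=17)
    paths = write_dataset(tmp_path, cfg)
    _, genes, table, truth, peaks, track = simulate_dataset(cfg)

    genes_back = assemble_transcriptome(read_bed12(paths["annotation"]))
    assert genes_back == genes

    table_back = read_counts_tsv(paths["counts"], paths["sample_sheet"])
    assert np.array_equal(table_back.counts, table.counts)
    assert table_back.samples == table.samples

    peaks_back = read_peaks_bed(paths["peaks"])
    assert [(p.chrom, p.start, p.end) for p in peaks_back.peaks] == [
        (p.chrom, p.start, p.end) for p in peaks.peaks
    ]

    truth_back = SimTruth.from_json(paths["truth"])
    assert truth_back.binders == truth.binders
    assert truth_back.peaked == truth.peaked

    track_back = read_bedgraph(paths["signal"], cfg.chrom_lengths())
    for g in genes[:5]:
        a = track.window_bin_means(g.chrom, g.tss - 5000, g.tss + 5000, 100)
        b = track_back.window_bin_means(g.chrom, g.tss - 5000, g.tss + 5000, 100)
        assert np.allclose(a, b, equal_nan=True)
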