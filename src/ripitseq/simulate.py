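"""Synthetic genome, RIPiT count data, and ChIP peaks/signal with ground truth.

The generator emulates, at desk scale, the four-condition tandem-IP design:
two wild-type pulldown replicates, an RNA-binding-dead point-mutant (F266A)
pulldown and an empty-vector pulldown, each with a matched input.  A small
multi-chromosome genome carries non-overlapping multi-exon genes on both
strands; per-gene baseline abundances are log-normal; read counts are
negative-binomial (gamma-Poisson) at per-sample depths defaulting to 5e5
reads — roughly a 100-fold scale-down of the tens of millions of mapped reads
per library the real experiment produced.  A designated binder subset carries
a log2 pulldown enrichment effect in the WT samples only (an optional leak
term puts residual enrichment in the controls).  ChIP peaks of configurable
width are centred on a subset of TSSs, optionally correlated with binder
status, over a constant-background signal track with bumps at peaked
promoters.  Everything is reproducible from the single seed, and the written
outputs round-trip through the package's readers.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import (
    GeneModel,
    TranscriptRecord,
    assemble_transcriptome,
    write_transcripts_bed12,
)
from .chip import Peak, PeakSet, SignalTrack
from .quantify import ReadInterval, Sample, SampleTable

CONDITION_LAYOUT = ("WT_rep1", "WT_rep2", "F266A", "vector")


@dataclass
class SimConfig:
    """Parameters of the synthetic study; the defaults are the study conditions."""

    seed: int
    n_chroms: int = 4
    chrom_length: int = 5_000_000
    n_genes: int = 2000
    min_exons: int = 1
    max_exons: int = 5
    exon_length_range: tuple[int, int] = (100, 800)
    intron_length_range: tuple[int, int] = (100, 1000)
    # per-sample expected sequencing depth (reads); one value for all samples
    # or a mapping sample_id -> depth
    depth: float = 5e5
    unassigned_fraction: float = 0.05
    # force every sample's library size to the nominal depth instead of the
    # realized column sum (an exactly-identical-depths design)
    equal_library_sizes: bool = False
    # log-normal baseline expression (natural-log scale)
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.2
    dispersion: float = 0.1  # NB: var = mu + dispersion * mu^2
    binder_fraction: float = 0.05
    binder_effect: float = 3.0  # log2 enrichment in WT pulldowns
    control_leak: float = 0.0  # residual log2 enrichment in F266A/vector pulldowns
    # ChIP layer
    chip_peak_fraction: float = 0.3
    binder_peak_fraction: float | None = None  # None -> same as chip_peak_fraction
    peak_width: int = 600
    signal_height: float = 10.0
    background: float = 0.5
    signal_resolution: int = 25
    read_length: int = 50

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("binder_fraction", "chip_peak_fraction", "unassigned_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.binder_peak_fraction is not None and not 0 <= self.binder_peak_fraction <= 1:
            raise ValueError("binder_peak_fraction must be in [0,1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.unassigned_fraction >= 1.0:
            raise ValueError("unassigned_fraction must be < 1")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


@dataclass
class SimTruth:
    """Generator ground truth for parameter-recovery tests."""

    seed: int
    binders: list[str]
    baseline: dict  # gene_id -> relative abundance weight
    effects: dict  # gene_id -> log2 WT pulldown effect
    peaked: list[str]  # gene_ids with a ChIP peak at the promoter
    library_sizes: dict  # sample_id -> realized library size

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    # independent, reproducible stream per stage (crc32 is process-stable)
    return np.random.default_rng([config.seed, zlib.crc32(stage.encode()) % (2**31)])


# ---------------------------------------------------------------------------
# Annotation


def simulate_annotation(config: SimConfig) -> tuple[list[TranscriptRecord], list[GeneModel]]:
    """Non-overlapping multi-exon genes on both strands, deterministic by seed."""
    rng = _rng(config, "annotation")
    records: list[TranscriptRecord] = []
    if config.n_genes == 0:
        return [], []
    chroms = config.chrom_names()
    slots_total = config.n_genes
    per_chrom = [slots_total // config.n_chroms] * config.n_chroms
    for i in range(slots_total % config.n_chroms):
        per_chrom[i] += 1
    max_span = (
        config.max_exons * config.exon_length_range[1]
        + (config.max_exons - 1) * config.intron_length_range[1]
    )
    gene_index = 0
    for chrom, n_slot in zip(chroms, per_chrom):
        if n_slot == 0:
            continue
        slot = config.chrom_length // n_slot
        if slot < max_span + 2:
            raise ValueError(
                f"cannot fit {n_slot} genes of span up to {max_span} bp on a "
                f"{config.chrom_length} bp chromosome"
            )
        for j in range(n_slot):
            gene_index += 1
            slot_start = j * slot
            n_exons = int(rng.integers(config.min_exons, config.max_exons + 1))
            exon_lens = rng.integers(*config.exon_length_range, size=n_exons)
            intron_lens = (
                rng.integers(*config.intron_length_range, size=n_exons - 1)
                if n_exons > 1
                else np.array([], dtype=int)
            )
            span = int(exon_lens.sum() + intron_lens.sum())
            offset = int(rng.integers(0, slot - span))
            start = slot_start + offset
            exons = []
            pos = start
            for k, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if k < len(intron_lens):
                    pos += int(intron_lens[k])
            strand = "+" if rng.random() < 0.5 else "-"
            symbol = f"SIMG{gene_index:05d}"
            records.append(
                TranscriptRecord(
                    transcript_id=f"{symbol}.1",
                    gene_symbol=symbol,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=exons[-1][1],
                    exons=tuple(exons),
                    source="sim",
                )
            )
    genes = assemble_transcriptome(records)
    return records, genes


# ---------------------------------------------------------------------------
# Counts


def design_samples() -> list[tuple[str, str, str, str | None]]:
    """(sample_id, condition, role, paired_input_id) for the 4x2 design."""
    out = []
    for cond in CONDITION_LAYOUT:
        out.append((f"{cond}_IP", cond, "pulldown", f"{cond}_input"))
        out.append((f"{cond}_input", cond, "input", None))
    return out


def simulate_counts(
    genes: Sequence[GeneModel], config: SimConfig
) -> tuple[SampleTable, SimTruth]:
    """NB counts for the 4-condition pulldown/input design, plus ground truth.

    Each condition is one lysate: gene abundances are the log-normal baseline
    times a per-condition gamma fluctuation (dispersion), shared between the
    condition's pulldown and its matched input — the abundance noise a matched
    input is designed to cancel.  Marginally every sample is therefore
    NB-distributed.  Pulldown means multiply the abundance by 2**effect, where
    effect is ``binder_effect`` for binders in WT samples, ``control_leak`` in
    F266A/vector, and 0 otherwise.  Relative abundances are renormalised per
    sample, so strong binders deplete the rest of the pulldown library (the
    compositional effect real immunoprecipitation shows).
    """
    rng = _rng(config, "counts")
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    lengths = np.array([g.exonic_length for g in genes], dtype=float)
    # abundance weight ~ lognormal expression per kb, times exonic length
    expr = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    baseline = expr * lengths / 1e3

    n_binders = round(config.binder_fraction * n)
    binder_idx = rng.choice(n, size=n_binders, replace=False)
    is_binder = np.zeros(n, dtype=bool)
    is_binder[binder_idx] = True

    spec = design_samples()
    depths = {
        sid: float(config.depth[sid]) if isinstance(config.depth, dict) else float(config.depth)
        for sid, *_ in spec
    }
    # per-condition lysate abundances (gamma-fluctuated baseline)
    abundance: dict[str, np.ndarray] = {}
    for cond in CONDITION_LAYOUT:
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            abundance[cond] = baseline * rng.gamma(shape, 1.0 / shape, size=n)
        else:
            abundance[cond] = baseline
    counts = np.zeros((n, len(spec)), dtype=np.int64)
    samples: list[Sample] = []
    for col, (sid, cond, role, paired) in enumerate(spec):
        effect = np.zeros(n)
        if role == "pulldown":
            if cond in ("WT_rep1", "WT_rep2"):
                effect[is_binder] = config.binder_effect
            else:
                effect[is_binder] = config.control_leak
        weights = abundance[cond] * np.exp2(effect)
        mu = depths[sid] * (1.0 - config.unassigned_fraction) * weights / weights.sum()
        counts[:, col] = rng.poisson(mu)
        assigned = int(counts[:, col].sum())
        if config.equal_library_sizes:
            library_size = max(assigned, round(depths[sid]))
        else:
            library_size = max(1, round(assigned / (1.0 - config.unassigned_fraction)))
        samples.append(
            Sample(
                sample_id=sid,
                condition=cond,
                role=role,
                library_size=library_size,
                paired_input_id=paired,
            )
        )
    table = SampleTable(genes=gene_ids, samples=samples, counts=counts)
    truth = SimTruth(
        seed=config.seed,
        binders=sorted(gene_ids[i] for i in np.flatnonzero(is_binder)),
        baseline={g: float(b) for g, b in zip(gene_ids, baseline)},
        effects={
            gene_ids[i]: float(config.binder_effect) for i in np.flatnonzero(is_binder)
        },
        peaked=[],
        library_sizes={s.sample_id: s.library_size for s in samples},
    )
    return table, truth


def simulate_reads(
    genes: Sequence[GeneModel], table: SampleTable, config: SimConfig
) -> dict[str, list[ReadInterval]]:
    """Materialise BED6-style reads whose midpoints land in each gene's exons.

    Per sample, each counted read is placed so that its midpoint is uniform
    over the gene's exon union; an additional ``unassigned_fraction`` of
    intergenic background reads tops the library up to its library size.
    """
    rng = _rng(config, "reads")
    half = config.read_length // 2
    out: dict[str, list[ReadInterval]] = {}
    for col, sample in enumerate(table.samples):
        reads: list[ReadInterval] = []
        for gi, g in enumerate(genes):
            c = int(table.counts[gi, col])
            if c == 0:
                continue
            offsets = rng.integers(0, g.exonic_length, size=c)
            # map exon-union offsets to genomic midpoints
            cum = 0
            bounds = []
            for s, e in g.exon_union:
                bounds.append((cum, cum + (e - s), s))
                cum += e - s
            starts = np.array([b[0] for b in bounds])
            genomic = np.empty(c, dtype=np.int64)
            which = np.searchsorted(starts, offsets, side="right") - 1
            for k in range(c):
                off0, _, gs = bounds[which[k]]
                genomic[k] = gs + (int(offsets[k]) - off0)
            for mid in genomic:
                start = max(0, int(mid) - half)
                reads.append(ReadInterval(g.chrom, start, start + config.read_length, g.strand))
        n_bg = sample.library_size - len(reads)
        chroms = config.chrom_names()
        for _ in range(max(0, n_bg)):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, config.chrom_length - config.read_length))
            reads.append(ReadInterval(chrom, start, start + config.read_length, "."))
        out[sample.sample_id] = reads
    return out


# ---------------------------------------------------------------------------
# ChIP layer


def simulate_chip(
    genes: Sequence[GeneModel], config: SimConfig, truth: SimTruth
) -> tuple[PeakSet, SignalTrack]:
    """Peaks at a configurable fraction of TSSs plus a bumpy signal track.

    When ``binder_peak_fraction`` is set, binder promoters are peaked with
    that probability (creating "both"-class genes at a controlled rate) and
    non-binder promoters with ``chip_peak_fraction``; ``truth.peaked`` is
    filled in place.
    """
    rng = _rng(config, "chip")
    binders = set(truth.binders)
    peaked: list[GeneModel] = []
    for g in genes:
        frac = (
            config.binder_peak_fraction
            if (config.binder_peak_fraction is not None and g.gene_id in binders)
            else config.chip_peak_fraction
        )
        if rng.random() < frac:
            peaked.append(g)
    truth.peaked = sorted(g.gene_id for g in peaked)

    half = config.peak_width // 2
    peaks = []
    res = config.signal_resolution
    bump_add: dict[str, dict[int, float]] = {c: {} for c in config.chrom_names()}
    for g in peaked:
        center = g.tss
        start = max(0, center - half)
        end = min(config.chrom_length, center + half)
        height = config.signal_height * float(rng.uniform(0.5, 1.5))
        peaks.append(Peak(g.chrom, start, end, score=height, name=f"peak_{g.gene_id}"))
        sd = config.peak_width / 4.0
        lo = max(0, center - 2 * config.peak_width)
        hi = min(config.chrom_length, center + 2 * config.peak_width)
        cells = bump_add[g.chrom]
        for cell in range(lo // res, (hi + res - 1) // res):
            x = cell * res + res / 2.0
            cells[cell] = cells.get(cell, 0.0) + height * float(
                np.exp(-0.5 * ((x - center) / sd) ** 2)
            )

    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in config.chrom_names():
        cells = bump_add[chrom]
        ivs: list[tuple[int, int, float]] = []
        pos = 0
        for cell in sorted(cells):
            s, e = cell * res, min((cell + 1) * res, config.chrom_length)
            if s > pos:
                ivs.append((pos, s, config.background))
            ivs.append((s, e, config.background + cells[cell]))
            pos = e
        if pos < config.chrom_length:
            ivs.append((pos, config.chrom_length, config.background))
        # merge runs with equal value to keep the track compact
        merged: list[tuple[int, int, float]] = []
        for s, e, v in ivs:
            if merged and merged[-1][2] == v and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e, v)
            else:
                merged.append((s, e, v))
        intervals[chrom] = merged
    track = SignalTrack(intervals, config.chrom_lengths())
    return PeakSet(peaks), track


# ---------------------------------------------------------------------------
# Whole dataset


def simulate_dataset(config: SimConfig):
    """Annotation + counts + ChIP layer in one call; returns all artifacts."""
    records, genes = simulate_annotation(config)
    table, truth = simulate_counts(genes, config)
    peaks, track = simulate_chip(genes, config, truth)
    return records, genes, table, truth, peaks, track


def write_dataset(outdir: str | Path, config: SimConfig) -> dict:
    """Simulate and write every artifact in the formats the readers consume."""
    from .chip import write_bedgraph, write_peaks_bed
    from .quantify import write_counts_tsv, write_sample_sheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, genes, table, truth, peaks, track = simulate_dataset(config)
    paths = {
        "annotation": outdir / "annotation.bed12",
        "counts": outdir / "counts.tsv",
        "sample_sheet": outdir / "samples.tsv",
        "peaks": outdir / "peaks.bed",
        "signal": outdir / "signal.bedgraph",
        "truth": outdir / "truth.json",
    }
    write_transcripts_bed12(records, paths["annotation"])
    write_counts_tsv(table, paths["counts"])
    write_sample_sheet(table.samples, paths["sample_sheet"])
    write_peaks_bed(peaks, paths["peaks"])
    write_bedgraph(track, paths["signal"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
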