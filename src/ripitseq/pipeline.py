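"""End-to-end orchestration: simulate or ingest, quantify, call, overlap.

``run_pipeline`` executes the stages in order — merged transcriptome, counts
(from a table or from mapped-read intervals), log2 RPKM expression matrix,
enrichment calls, ChIP promoter overlap with Fisher test and three-way
classification, top-quintile restriction, and per-class metagene profiles —
writing fixed-name outputs under a run directory together with a JSON
manifest of parameters, per-stage tallies and output checksums.  Stage
outputs are pure functions of (inputs, parameters, seed); rerunning an
identical configuration reproduces the manifest byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import annotation as ann
from . import chip as chipmod
from . import enrichment as enr
from . import quantify as qt
from .simulate import SimConfig, SimTruth, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: str
    # either simulate=True (with seed / sim overrides) or explicit input paths
    simulate: bool = False
    seed: int | None = None
    sim: dict = field(default_factory=dict)
    annotation_sources: list = field(default_factory=list)  # {path, format, label}
    counts: str | None = None
    sample_sheet: str | None = None
    reads: dict = field(default_factory=dict)  # sample_id -> BED6 path
    peaks: str | None = None
    signal: str | None = None
    # parameters
    pseudocount: float = 1.0
    promoter_upstream: int = 2000
    promoter_downstream: int = 1000
    fisher_alternative: str = "greater"
    metagene_window: int = 5000
    metagene_bins: int = 100
    quintile_mode: str = "track"  # 'track' or 'peak_score'

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        if self.simulate:
            if self.seed is None:
                raise ValueError("simulation requires a seed")
        else:
            if not self.annotation_sources:
                raise ValueError("at least one annotation source is required")
            for src in self.annotation_sources:
                if not Path(src["path"]).exists():
                    raise ValueError(f"annotation source not found: {src['path']}")
            if self.counts is None and not self.reads:
                raise ValueError("either a counts table or per-sample reads are required")
            if self.sample_sheet is None:
                raise ValueError("a sample sheet is required")
            for p in filter(None, [self.counts, self.sample_sheet, self.peaks, self.signal]):
                if not Path(p).exists():
                    raise ValueError(f"input not found: {p}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.fisher_alternative not in ("greater", "two-sided"):
            raise ValueError("fisher_alternative must be 'greater' or 'two-sided'")
        if self.quintile_mode not in ("track", "peak_score"):
            raise ValueError("quintile_mode must be 'track' or 'peak_score'")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "parameters": {
            "pseudocount": config.pseudocount,
            "promoter_upstream": config.promoter_upstream,
            "promoter_downstream": config.promoter_downstream,
            "fisher_alternative": config.fisher_alternative,
            "metagene_window": config.metagene_window,
            "metagene_bins": config.metagene_bins,
            "quintile_mode": config.quintile_mode,
            "seed": config.seed,
            "simulate": config.simulate,
        },
        "stages": {},
        "outputs": {},
    }

    # Stage 0: simulation (optional)
    truth: SimTruth | None = None
    chrom_lengths = None
    if config.simulate:
        sim_cfg = SimConfig(seed=config.seed, **config.sim)
        sim_paths = write_dataset(outdir / "sim", sim_cfg)
        truth = SimTruth.from_json(sim_paths["truth"])
        chrom_lengths = sim_cfg.chrom_lengths()
        config.annotation_sources = [
            {"path": sim_paths["annotation"], "format": "bed12", "label": "sim"}
        ]
        config.counts = sim_paths["counts"]
        config.sample_sheet = sim_paths["sample_sheet"]
        config.peaks = sim_paths["peaks"]
        config.signal = sim_paths["signal"]
        manifest["stages"]["simulate"] = {
            "n_binders": len(truth.binders),
            "n_peaked": len(truth.peaked),
        }
        manifest["inputs"] = {k: _sha256(Path(p)) for k, p in sim_paths.items()}
    else:
        manifest["inputs"] = {
            p: _sha256(Path(p))
            for p in filter(
                None,
                [s["path"] for s in config.annotation_sources]
                + [config.counts, config.sample_sheet, config.peaks, config.signal]
                + list(config.reads.values()),
            )
        }

    # Stage 1: transcriptome assembly
    records = []
    for src in config.annotation_sources:
        records.extend(
            ann.read_annotation(src["path"], src["format"], src.get("label", ""))
        )
    genes = ann.assemble_transcriptome(records)
    ann.write_bed12(genes, outdir / "transcriptome.bed12")
    ann.write_gene_table(genes, outdir / "gene_table.tsv")
    manifest["stages"]["assemble"] = {
        "n_transcripts": len(records),
        "n_genes": len(genes),
    }
    logger.info("assembled %d genes from %d transcripts", len(genes), len(records))

    # Stage 2: counts
    if config.counts is not None:
        table = qt.read_counts_tsv(config.counts, config.sample_sheet)
    else:
        samples = qt.read_sample_sheet(config.sample_sheet)
        counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
        tallies_all = {}
        for j, s in enumerate(samples):
            if s.sample_id not in config.reads:
                raise ValueError(f"no reads file for sample {s.sample_id}")
            reads = qt.read_bed6(config.reads[s.sample_id])
            counts[:, j], tallies = qt.count_reads(reads, genes)
            tallies_all[s.sample_id] = tallies
        table = qt.SampleTable([g.gene_id for g in genes], samples, counts)
        qt.write_counts_tsv(table, outdir / "counts.tsv")
        manifest["stages"]["count"] = tallies_all
    manifest["stages"]["counts_loaded"] = {
        "n_genes": len(table.genes),
        "n_samples": len(table.samples),
        "library_sizes": {s.sample_id: s.library_size for s in table.samples},
    }

    # Stage 3: expression
    order = {g.gene_id: g for g in genes}
    if set(table.genes) != set(order):
        raise ValueError("count table and assembled transcriptome disagree on gene ids")
    gene_models = [order[g] for g in table.genes]
    expr = qt.build_expression_matrix(table, gene_models, config.pseudocount)
    expr.to_frame().to_csv(outdir / "expression.tsv", sep="\t")
    manifest["stages"]["quantify"] = {"pseudocount": config.pseudocount}

    # Stage 4: enrichment calling
    results, frame = enr.call_all(expr, table.samples)
    enr.write_enrichment_tsv(frame, outdir / "enrichment.tsv")
    enr.write_enriched_list(frame, outdir / "enriched_genes.txt")
    enr.write_score_matrix(frame, outdir / "score_matrix.tsv")
    rip_set = enr.enriched_gene_set(results)
    manifest["stages"]["call"] = {"n_enriched": len(rip_set)}
    logger.info("%d of %d genes called WT-enriched", len(rip_set), len(table.genes))

    if truth is not None:
        binder_set = set(truth.binders)
        tp = len(rip_set & binder_set)
        fp = len(rip_set - binder_set)
        fn = len(binder_set - rip_set)
        tn = len(table.genes) - tp - fp - fn
        manifest["stages"]["recovery"] = {
            "sensitivity": tp / max(1, tp + fn),
            "specificity": tn / max(1, tn + fp),
            "n_true_binders": len(binder_set),
        }

    # Stage 5: ChIP overlap, classification, quintile
    if config.peaks is not None:
        peaks = chipmod.read_peaks_bed(config.peaks)
        track = (
            chipmod.read_bedgraph(config.signal, chrom_lengths)
            if config.signal is not None
            else None
        )
        universe = set(table.genes)
        chip_set = chipmod.chip_bound_genes(
            gene_models, peaks, config.promoter_upstream, config.promoter_downstream
        )
        overlap = chipmod.fisher_overlap(
            universe, chip_set, rip_set, config.fisher_alternative
        )
        chipmod.write_classes_tsv(overlap.classes, outdir / "classes.tsv")

        signal_by_gene = chipmod.promoter_signal(
            [order[g] for g in sorted(chip_set)],
            track if config.quintile_mode == "track" else None,
            peaks if config.quintile_mode == "peak_score" else None,
            config.promoter_upstream,
            config.promoter_downstream,
        )
        top_set = chipmod.top_quintile_promoters(signal_by_gene)
        top_overlap = (
            chipmod.fisher_overlap(universe, top_set, rip_set, config.fisher_alternative)
            if top_set
            else None
        )
        overlap_json = {
            "universe_size": overlap.universe_size,
            "n_chip": overlap.n_chip,
            "n_rip": overlap.n_rip,
            "n_both": overlap.n_both,
            "odds_ratio": overlap.odds_ratio,
            "p_value": overlap.p_value,
            "alternative": overlap.alternative,
            "class_counts": overlap.class_counts(),
            "top_quintile": None
            if top_overlap is None
            else {
                "n_top": top_overlap.n_chip,
                "n_both": top_overlap.n_both,
                "odds_ratio": top_overlap.odds_ratio,
                "p_value": top_overlap.p_value,
            },
        }
        with open(outdir / "overlap.json", "w") as fh:
            json.dump(overlap_json, fh, indent=1, sort_keys=True, allow_nan=True)
        manifest["stages"]["overlap"] = overlap_json

        # Stage 6: metagene profiles per class
        if track is not None:
            for label in chipmod.CLASS_LABELS:
                members = [
                    order[g] for g, cl in overlap.classes.items() if cl == label
                ]
                profile = chipmod.metagene_profile(
                    track,
                    sorted(members, key=lambda g: g.gene_id),
                    config.metagene_window,
                    config.metagene_bins,
                    class_label=label,
                )
                profile.to_frame().to_csv(
                    outdir / f"metagene_{label}.tsv", sep="\t", index=False
                )
            manifest["stages"]["metagene"] = {
                "window": config.metagene_window,
                "bins": config.metagene_bins,
                "classes": list(chipmod.CLASS_LABELS),
            }

    # checksums of every produced output
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
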