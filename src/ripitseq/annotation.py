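"""Gene annotation readers and non-redundant transcriptome assembly.

Transcript records from multiple annotation sources (BED12, GTF) are merged
into one strand-aware gene model per locus: transcripts sharing a gene symbol
collapse into a single gene, while unsymboled transcripts (e.g. lincRNA
predictions) are clustered by single-linkage exonic overlap on the same
strand.  The resulting :class:`GeneModel` — exon union, exonic length and
TSS — is the unit of quantification for every downstream stage.

All coordinates are 0-based half-open internally; GTF (1-based inclusive) is
converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

STRANDS = ("+", "-")


class AnnotationParseError(ValueError):
    """Raised for a malformed annotation line; message names the line number."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A single transcript from one annotation source.

    ``exons`` are sorted, non-overlapping, 0-based half-open intervals
    contained in ``[tx_start, tx_end)``.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[Interval, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.transcript_id}: strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.transcript_id}: tx_start must be < tx_end")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(
                    f"{self.transcript_id}: exon ({s},{e}) outside transcript span "
                    f"[{self.tx_start},{self.tx_end})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = e


@dataclass(frozen=True)
class GeneModel:
    """One merged gene: exon union, exonic length, strand-aware TSS."""

    gene_id: str
    chrom: str
    strand: str
    exon_union: tuple[Interval, ...]
    exonic_length: int
    tss: int
    member_transcripts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.exonic_length <= 0:
            raise ValueError(f"{self.gene_id}: exonic_length must be positive")
        if self.exonic_length != sum(e - s for s, e in self.exon_union):
            raise ValueError(f"{self.gene_id}: exonic_length inconsistent with exon_union")

    @property
    def start(self) -> int:
        return self.exon_union[0][0]

    @property
    def end(self) -> int:
        return self.exon_union[-1][1]


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Union of half-open intervals; adjacent intervals (end == start) merge."""
    ivs = sorted(intervals)
    if not ivs:
        return ()
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


# ---------------------------------------------------------------------------
# Readers


def read_bed12(path: str | Path, source_label: str = "") -> list[TranscriptRecord]:
    """Read transcripts from a BED12 file (native 0-based half-open)."""
    records: list[TranscriptRecord] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3]
                strand = fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise AnnotationParseError(
                    f"{path}:{lineno}: blockCount={n_blocks} does not match "
                    f"{len(sizes)} sizes / {len(offsets)} starts"
                )
            exons = tuple((start + o, start + o + z) for o, z in zip(offsets, sizes))
            symbol = fields[12] if len(fields) > 12 else ""
            try:
                records.append(
                    TranscriptRecord(
                        transcript_id=name,
                        gene_symbol=symbol,
                        chrom=chrom,
                        strand=strand,
                        tx_start=start,
                        tx_end=end,
                        exons=exons,
                        source=source_label,
                    )
                )
            except ValueError as exc:
                logger.warning("%s:%d: record rejected: %s", path, lineno, exc)
    if not records:
        logger.warning("%s: no transcript records parsed (empty annotation)", path)
    return records


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str | Path, source_label: str = "") -> list[TranscriptRecord]:
    """Read transcripts from GTF exon features (1-based inclusive -> half-open)."""
    path = Path(path)
    exons_by_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                start = int(fields[3]) - 1  # to 0-based half-open
                end = int(fields[4])
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            attrs = _parse_gtf_attributes(fields[8])
            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise AnnotationParseError(f"{path}:{lineno}: missing transcript_id attribute")
            entry = exons_by_tx.setdefault(
                tx_id,
                {
                    "chrom": fields[0],
                    "strand": fields[6],
                    "symbol": attrs.get("gene_name", attrs.get("gene_id", "")),
                    "exons": [],
                },
            )
            entry["exons"].append((start, end))
            if len(entry["exons"]) == 1:
                order.append(tx_id)
    records: list[TranscriptRecord] = []
    for tx_id in order:
        entry = exons_by_tx[tx_id]
        exons = merge_intervals(entry["exons"])
        try:
            records.append(
                TranscriptRecord(
                    transcript_id=tx_id,
                    gene_symbol=entry["symbol"],
                    chrom=entry["chrom"],
                    strand=entry["strand"],
                    tx_start=exons[0][0],
                    tx_end=exons[-1][1],
                    exons=exons,
                    source=source_label,
                )
            )
        except ValueError as exc:
            logger.warning("%s: transcript %s rejected: %s", path, tx_id, exc)
    if not records:
        logger.warning("%s: no transcript records parsed (empty annotation)", path)
    return records


def read_annotation(
    path: str | Path, format: str, source_label: str = ""
) -> list[TranscriptRecord]:
    """Dispatch to the BED12 or GTF reader by ``format``."""
    if format == "bed12":
        return read_bed12(path, source_label)
    if format == "gtf":
        return read_gtf(path, source_label)
    raise ValueError(f"unknown annotation format {format!r} (expected 'bed12' or 'gtf')")


# ---------------------------------------------------------------------------
# Assembly


def _cluster_by_overlap(records: list[TranscriptRecord]) -> list[list[TranscriptRecord]]:
    """Single-linkage clustering of transcripts by exonic overlap (same chrom/strand)."""
    spans = sorted(records, key=lambda r: (r.exons[0][0], r.exons[-1][1], r.transcript_id))
    clusters: list[list[TranscriptRecord]] = []
    cluster_union: tuple[Interval, ...] = ()
    for rec in spans:
        overlaps = any(
            s < ue and us < e for s, e in rec.exons for us, ue in cluster_union
        )
        if clusters and overlaps:
            clusters[-1].append(rec)
            cluster_union = merge_intervals(cluster_union + rec.exons)
        else:
            clusters.append([rec])
            cluster_union = rec.exons
    return clusters


def _gene_from_members(members: Sequence[TranscriptRecord], gene_id: str | None) -> GeneModel:
    chrom = members[0].chrom
    strand = members[0].strand
    union = merge_intervals([iv for m in members for iv in m.exons])
    # TSS: the most 5' transcript start with respect to strand
    if strand == "+":
        tss = min(m.tx_start for m in members)
    else:
        tss = max(m.tx_end for m in members)
    if gene_id is None:
        gene_id = f"LOCUS_{chrom}_{union[0][0]}_{strand}"
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exon_union=union,
        exonic_length=sum(e - s for s, e in union),
        tss=tss,
        member_transcripts=tuple(sorted(m.transcript_id for m in members)),
    )


def assemble_transcriptome(records: Sequence[TranscriptRecord]) -> list[GeneModel]:
    """Merge transcript records into a non-redundant, gene-level transcriptome.

    Transcripts sharing a ``gene_symbol`` (on the same chromosome and strand)
    form one gene; unsymboled transcripts are clustered by single-linkage
    exonic overlap.  Output is sorted by (chrom, start, gene_id) and is
    invariant to input order.
    """
    if not records:
        raise ValueError("assemble_transcriptome requires at least one transcript record")
    by_symbol: dict[tuple[str, str, str], list[TranscriptRecord]] = {}
    unsymboled: dict[tuple[str, str], list[TranscriptRecord]] = {}
    for rec in records:
        if rec.gene_symbol:
            by_symbol.setdefault((rec.gene_symbol, rec.chrom, rec.strand), []).append(rec)
        else:
            unsymboled.setdefault((rec.chrom, rec.strand), []).append(rec)

    genes: list[GeneModel] = []
    for (symbol, _chrom, _strand), members in by_symbol.items():
        genes.append(_gene_from_members(members, symbol))
    for (_chrom, _strand), members in unsymboled.items():
        for cluster in _cluster_by_overlap(members):
            sources = {m.source for m in cluster}
            if len(sources) > 1:
                logger.warning(
                    "overlap-grouping merged unsymboled transcripts across sources %s "
                    "into one locus at %s:%d",
                    sorted(sources), cluster[0].chrom, cluster[0].exons[0][0],
                )
            genes.append(_gene_from_members(cluster, None))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def genes_to_transcripts(genes: Sequence[GeneModel]) -> list[TranscriptRecord]:
    """Re-express assembled genes as single-transcript records (for round trips)."""
    out = []
    for g in genes:
        symbol = "" if g.gene_id.startswith("LOCUS_") else g.gene_id
        out.append(
            TranscriptRecord(
                transcript_id=g.gene_id,
                gene_symbol=symbol,
                chrom=g.chrom,
                strand=g.strand,
                tx_start=g.start,
                tx_end=g.end,
                exons=g.exon_union,
                source="assembled",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Writers


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """One BED12 line per gene; blocks are the exon union."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exon_union)
            offsets = ",".join(str(s - g.start) for s, _ in g.exon_union)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(g.exon_union)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def write_transcripts_bed12(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    """BED12 + a 13th gene_symbol column (read back by :func:`read_bed12`)."""
    with open(path, "w") as fh:
        for r in records:
            sizes = ",".join(str(e - s) for s, e in r.exons)
            offsets = ",".join(str(s - r.tx_start) for s, _ in r.exons)
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.tx_start),
                        str(r.tx_end),
                        r.transcript_id,
                        "0",
                        r.strand,
                        str(r.tx_start),
                        str(r.tx_end),
                        "0",
                        str(len(r.exons)),
                        sizes,
                        offsets,
                        r.gene_symbol,
                    ]
                )
                + "\n"
            )


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    """TSV summary: gene_id, chrom, strand, tss, exonic_length, n_transcripts."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\texonic_length\tn_transcripts\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.exonic_length}\t"
                f"{len(g.member_transcripts)}\n"
            )
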