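"""Read counting against gene exon models and log2 RPKM quantification.

A read is assigned to a gene when its midpoint falls inside the gene's exon
union (strand-agnostic); if several genes' exon unions contain the midpoint
the gene with the smaller exonic length wins, ties broken by gene_id, and the
ambiguity is tallied.  Counts are converted to RPKM
(count * 1e9 / (library_size * exonic_length)) and log2-transformed with a
pseudocount, the expression unit used by the enrichment caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel

logger = logging.getLogger(__name__)

CONDITIONS = ("WT_rep1", "WT_rep2", "F266A", "vector")
ROLES = ("pulldown", "input")


@dataclass(frozen=True)
class ReadInterval:
    """A mapped read as a genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"read {self.chrom}:{self.start}-{self.end}: start must be < end")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Sample:
    """Sample descriptor: condition, pulldown/input role, pairing, depth."""

    sample_id: str
    condition: str
    role: str
    library_size: int
    paired_input_id: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"sample {self.sample_id}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )
        if self.role not in ROLES:
            raise ValueError(f"sample {self.sample_id}: role must be pulldown or input")
        if self.library_size <= 0:
            raise ValueError(f"sample {self.sample_id}: library_size must be positive")
        if self.role == "pulldown" and not self.paired_input_id:
            raise ValueError(f"pulldown sample {self.sample_id} has no paired_input_id")


@dataclass
class SampleTable:
    """Gene x sample read-count matrix with library sizes and sample roles."""

    genes: list[str]
    samples: list[Sample]
    counts: np.ndarray  # shape (n_genes, n_samples), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        ids = {s.sample_id for s in self.samples}
        for s in self.samples:
            if s.role == "pulldown" and s.paired_input_id not in ids:
                raise ValueError(
                    f"pulldown {s.sample_id}: paired_input_id {s.paired_input_id!r} "
                    "not present in sample sheet"
                )
        colsums = self.counts.sum(axis=0)
        for s, tot in zip(self.samples, colsums):
            if s.library_size < tot:
                raise ValueError(
                    f"sample {s.sample_id}: library_size {s.library_size} smaller than "
                    f"assigned count sum {tot}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def sample(self, sample_id: str) -> Sample:
        return self.samples[self.sample_ids.index(sample_id)]


@dataclass
class ExpressionMatrix:
    """Gene x sample log2(RPKM + pseudocount) matrix."""

    genes: list[str]
    sample_ids: list[str]
    values: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.sample_ids)):
            raise ValueError("expression values shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# Counting


def build_exon_index(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree of exon-union segments -> gene index."""
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exon_union:
            tree.addi(s, e, i)
    return trees


def count_reads(
    reads: Iterable[ReadInterval], genes: Sequence[GeneModel]
) -> tuple[np.ndarray, dict[str, int]]:
    """Assign each read to at most one gene by the midpoint-in-exon-union rule.

    Returns the per-gene count vector (aligned with ``genes``) and tallies:
    ``assigned``, ``unassigned`` (midpoint in no exon union or unknown chrom),
    ``ambiguous`` (midpoint in several genes; still assigned, to the gene with
    the smaller exonic length, ties by gene_id).
    """
    trees = build_exon_index(genes)
    counts = np.zeros(len(genes), dtype=np.int64)
    tallies = {"assigned": 0, "unassigned": 0, "ambiguous": 0}
    for read in reads:
        tree = trees.get(read.chrom)
        hits = tree[read.midpoint] if tree is not None else set()
        if not hits:
            tallies["unassigned"] += 1
            continue
        idxs = {h.data for h in hits}
        if len(idxs) > 1:
            tallies["ambiguous"] += 1
            winner = min(idxs, key=lambda i: (genes[i].exonic_length, genes[i].gene_id))
        else:
            winner = next(iter(idxs))
        counts[winner] += 1
        tallies["assigned"] += 1
    if tallies["ambiguous"]:
        logger.warning("%d reads had ambiguous midpoint assignment", tallies["ambiguous"])
    return counts, tallies


# ---------------------------------------------------------------------------
# RPKM


def compute_rpkm(count: float, library_size: int, exonic_length: int) -> float:
    """RPKM = count * 1e9 / (library_size * exonic_length)."""
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    if exonic_length <= 0:
        raise ValueError(f"exonic_length must be positive, got {exonic_length}")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * 1e9 / (library_size * exonic_length)


def log2_transform(rpkm: float, pseudocount: float = 1.0) -> float:
    """log2(rpkm + pseudocount); pseudocount bounds the value below."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if rpkm < 0:
        raise ValueError("rpkm must be non-negative")
    return float(np.log2(rpkm + pseudocount))


def build_expression_matrix(
    table: SampleTable, genes: Sequence[GeneModel], pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(RPKM + pseudocount) for every gene and sample of a count table."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    model_ids = [g.gene_id for g in genes]
    if model_ids != table.genes:
        missing = sorted(set(table.genes) ^ set(model_ids))
        raise ValueError(
            "gene sets of count table and gene models disagree; offending ids: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    lengths = np.array([g.exonic_length for g in genes], dtype=float)
    depths = np.array([s.library_size for s in table.samples], dtype=float)
    rpkm = table.counts * 1e9 / (depths[None, :] * lengths[:, None])
    return ExpressionMatrix(
        genes=list(table.genes),
        sample_ids=table.sample_ids,
        values=np.log2(rpkm + pseudocount),
        pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------------
# I/O: BED6 reads, counts TSV, sample sheet TSV


def read_bed6(path: str | Path) -> list[ReadInterval]:
    reads = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                strand = fields[5] if len(fields) > 5 else "."
                reads.append(ReadInterval(fields[0], int(fields[1]), int(fields[2]), strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return reads


def write_bed6(reads: Sequence[ReadInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t0\t{r.strand}\n")


def write_counts_tsv(table: SampleTable, path: str | Path) -> None:
    df = pd.DataFrame(table.counts, index=table.genes, columns=table.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_sample_sheet(samples: Sequence[Sample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "condition": s.condition,
            "role": s.role,
            "paired_input_id": s.paired_input_id or "",
            "library_size": s.library_size,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[Sample]:
    df = pd.read_csv(path, sep="\t", dtype={"paired_input_id": str}, keep_default_na=False)
    samples = []
    for _, row in df.iterrows():
        samples.append(
            Sample(
                sample_id=str(row["sample_id"]),
                condition=str(row["condition"]),
                role=str(row["role"]),
                library_size=int(row["library_size"]),
                paired_input_id=str(row["paired_input_id"]) or None,
            )
        )
    return samples


def read_counts_tsv(counts_path: str | Path, sheet_path: str | Path) -> SampleTable:
    samples = read_sample_sheet(sheet_path)
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    order = [s.sample_id for s in samples]
    missing = [sid for sid in order if sid not in df.columns]
    if missing:
        raise ValueError(f"count table missing sample columns: {missing}")
    return SampleTable(
        genes=[str(g) for g in df.index],
        samples=samples,
        counts=df[order].to_numpy(dtype=np.int64),
    )
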