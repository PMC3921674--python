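"""Promoter-window ChIP overlap, Fisher's exact test, quintiles, metagenes.

A gene is ChIP-bound when its promoter window (default 2 kb upstream to 1 kb
downstream of the TSS, strand-aware) intersects at least one peak by >= 1 bp
under half-open coordinates.  The overlap between the ChIP-bound and
RIP-enriched gene sets over a fixed gene universe is summarised as a 2x2
contingency table with an exact hypergeometric (Fisher) p-value, genes are
classified as both / chip_only / rip_only / neither, and per-class metagene
profiles average a coverage track in uniform bins across a strand-oriented
window anchored at each TSS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel

logger = logging.getLogger(__name__)

CLASS_LABELS = ("both", "chip_only", "rip_only", "neither")


@dataclass(frozen=True)
class PromoterInterval:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.score < 0:
            raise ValueError("peak score must be >= 0")


@dataclass
class PeakSet:
    peaks: list[Peak]

    def __len__(self) -> int:
        return len(self.peaks)

    def index(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for p in self.peaks:
            trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
        return trees


@dataclass
class OverlapResult:
    """2x2 contingency of ChIP-bound x RIP-enriched over a gene universe."""

    universe_size: int
    n_chip: int
    n_rip: int
    n_both: int
    odds_ratio: float
    p_value: float
    alternative: str
    classes: dict  # gene_id -> class label

    @property
    def table(self) -> list[list[int]]:
        a = self.n_both
        b = self.n_chip - self.n_both
        c = self.n_rip - self.n_both
        d = self.universe_size - self.n_chip - self.n_rip + self.n_both
        return [[a, b], [c, d]]

    def class_counts(self) -> dict:
        counts = {label: 0 for label in CLASS_LABELS}
        for label in self.classes.values():
            counts[label] += 1
        return counts


@dataclass
class MetageneProfile:
    """TSS-anchored, strand-oriented binned mean of a coverage signal."""

    bin_centers: np.ndarray  # bp offsets relative to TSS, 5'->3'
    mean_signal: np.ndarray
    n_per_bin: np.ndarray
    n_genes: int
    class_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean_signal": self.mean_signal,
                "n": self.n_per_bin,
            }
        )


# ---------------------------------------------------------------------------
# Promoters and bound genes


def promoter_interval(
    gene: GeneModel, upstream: int = 2000, downstream: int = 1000
) -> PromoterInterval:
    """Strand-aware promoter window around the TSS, clipped at position 0.

    On + strand: [tss - upstream, tss + downstream); on - strand the window is
    mirrored so that "upstream" still means 5' of the gene.
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    return PromoterInterval(gene.gene_id, gene.chrom, max(0, start), end, gene.strand)


def chip_bound_genes(
    genes: Sequence[GeneModel],
    peaks: PeakSet,
    upstream: int = 2000,
    downstream: int = 1000,
) -> set[str]:
    """Genes whose promoter window intersects >= 1 peak by >= 1 bp."""
    trees = peaks.index()
    bound: set[str] = set()
    for g in genes:
        promoter = promoter_interval(g, upstream, downstream)
        tree = trees.get(promoter.chrom)
        if tree is not None and tree.overlap(promoter.start, promoter.end):
            bound.add(g.gene_id)
    return bound


# ---------------------------------------------------------------------------
# Fisher's exact test (exact integer arithmetic)


def fisher_pvalue(k: int, K: int, n: int, N: int, alternative: str = "greater") -> float:
    """Exact Fisher p-value for observing k successes drawing n from N with K marked.

    The 2x2 table is [[k, K-k], [n-k, N-K-n+k]].  ``greater`` sums the upper
    hypergeometric tail; ``two-sided`` sums all outcomes whose probability does
    not exceed the observed one (exact integer comparison, no float epsilon).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    lo, hi = max(0, K + n - N), min(K, n)
    if not lo <= k <= hi:
        raise ValueError(f"k={k} outside hypergeometric support [{lo},{hi}]")
    weights = [math.comb(K, j) * math.comb(N - K, n - j) for j in range(lo, hi + 1)]
    total = math.comb(N, n)
    obs = weights[k - lo]
    if alternative == "greater":
        num = sum(weights[k - lo :])
    elif alternative == "two-sided":
        num = sum(w for w in weights if w <= obs)
    else:
        raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")
    return float(Fraction(num, total))


def fisher_overlap(
    universe: Iterable[str],
    set_a: Iterable[str],
    set_b: Iterable[str],
    alternative: str = "greater",
) -> OverlapResult:
    """Fisher's exact test of overlap between two gene sets over a universe.

    ``set_a`` plays the ChIP-bound role and ``set_b`` the RIP-enriched role in
    the stored counts; the test itself is symmetric.  The odds ratio is the
    sample cross-product ratio (inf when a zero cell makes the denominator 0,
    nan for 0/0).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    p = fisher_pvalue(a, len(set_a), len(set_b), len(universe), alternative)
    return OverlapResult(
        universe_size=len(universe),
        n_chip=len(set_a),
        n_rip=len(set_b),
        n_both=a,
        odds_ratio=odds,
        p_value=p,
        alternative=alternative,
        classes=classify_genes(universe, set_a, set_b),
    )


def classify_genes(
    universe: Iterable[str], chip_set: Iterable[str], rip_set: Iterable[str]
) -> dict:
    """Label each universe gene both / chip_only / rip_only / neither."""
    chip_set, rip_set = set(chip_set), set(rip_set)
    out = {}
    for g in universe:
        in_chip, in_rip = g in chip_set, g in rip_set
        if in_chip and in_rip:
            out[g] = "both"
        elif in_chip:
            out[g] = "chip_only"
        elif in_rip:
            out[g] = "rip_only"
        else:
            out[g] = "neither"
    return out


# ---------------------------------------------------------------------------
# Top-quintile promoters


def top_quintile_promoters(signal: Mapping[str, float]) -> set[str]:
    """The ceil(n/5) genes with the highest per-promoter signal.

    Boundary ties are resolved deterministically by gene_id order and logged.
    """
    n = len(signal)
    if n == 0:
        return set()
    k = math.ceil(n / 5)
    ranked = sorted(signal.items(), key=lambda kv: (-kv[1], kv[0]))
    if k < n and ranked[k - 1][1] == ranked[k][1]:
        logger.warning(
            "top-quintile boundary tie at signal %.6g; resolved by gene_id order",
            ranked[k - 1][1],
        )
    return {g for g, _ in ranked[:k]}


# ---------------------------------------------------------------------------
# Signal track and metagene profiles


class SignalTrack:
    """Piecewise-constant non-negative coverage over chromosomes.

    Stored per chromosome as sorted, non-overlapping (starts, ends, values)
    arrays; positions not covered by any interval have value 0 within the
    chromosome bounds and are out-of-range beyond them.
    """

    def __init__(
        self,
        intervals: Mapping[str, Sequence[tuple[int, int, float]]],
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths or {})
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            values = np.array([v for _, _, v in ivs], dtype=float)
            if np.any(values < 0):
                raise ValueError(f"{chrom}: signal values must be >= 0")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: signal intervals overlap")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = values
            # cumulative integral of the step function at interval boundaries
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self.chrom_lengths.setdefault(chrom, int(ends[-1]) if len(ends) else 0)

    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def _integral_upto(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, pos) for an array of positions."""
        starts, ends = self._starts[chrom], self._ends[chrom]
        cum, values = self._cum[chrom], self._values[chrom]
        if not len(starts):
            return np.zeros_like(pos, dtype=float)
        idx = np.searchsorted(ends, pos, side="left")  # first interval not fully left of pos
        total = cum[idx].astype(float)
        inside = idx < len(starts)
        ii = idx[inside]
        overlap = np.clip(pos[inside] - starts[ii], 0, ends[ii] - starts[ii])
        total[inside] += values[ii] * overlap
        return total

    def window_bin_means(
        self, chrom: str, start: int, end: int, n_bins: int
    ) -> np.ndarray:
        """Mean signal in n_bins equal bins over [start, end); NaN where a bin
        extends beyond the chromosome bounds."""
        if chrom not in self._starts:
            return np.full(n_bins, np.nan)
        length = self.chrom_lengths.get(chrom, int(self._ends[chrom][-1]))
        edges = start + (end - start) * np.arange(n_bins + 1) / n_bins
        edges_i = np.rint(edges).astype(np.int64)
        clipped = np.clip(edges_i, 0, length)
        integral = self._integral_upto(chrom, clipped)
        widths = np.diff(edges_i).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(widths > 0, np.diff(integral) / np.maximum(widths, 1), np.nan)
        out_of_bounds = (edges_i[:-1] < 0) | (edges_i[1:] > length)
        means[out_of_bounds] = np.nan
        return means

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over a single interval, clipped to chromosome bounds."""
        if chrom not in self._starts:
            return 0.0
        length = self.chrom_lengths.get(chrom, int(self._ends[chrom][-1]))
        a, b = max(0, start), min(length, end)
        if b <= a:
            return 0.0
        integral = self._integral_upto(chrom, np.array([a, b], dtype=np.int64))
        return float((integral[1] - integral[0]) / (b - a))


def metagene_profile(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    window: int = 5000,
    n_bins: int = 100,
    class_label: str = "",
) -> MetageneProfile:
    """Average a coverage track around TSSs, strand-oriented 5'->3'.

    Each gene contributes n_bins bin means over [tss - window, tss + window);
    minus-strand genes are reversed so bin 1 is always upstream.  Bins falling
    outside chromosome bounds are missing for that gene and excluded from the
    cross-gene mean.
    """
    width = 2 * window / n_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for g in genes:
        means = track.window_bin_means(g.chrom, g.tss - window, g.tss + window, n_bins)
        if g.strand == "-":
            means = means[::-1]
        ok = np.isfinite(means)
        sums[ok] += means[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        mean_signal = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = -window + width * (np.arange(n_bins) + 0.5)
    return MetageneProfile(
        bin_centers=centers,
        mean_signal=mean_signal,
        n_per_bin=counts,
        n_genes=len(genes),
        class_label=class_label,
    )


def promoter_signal(
    genes: Sequence[GeneModel],
    track: SignalTrack | None,
    peaks: PeakSet | None = None,
    upstream: int = 2000,
    downstream: int = 1000,
) -> dict[str, float]:
    """Per-promoter ranking signal: mean track coverage over the promoter
    window, falling back to the max overlapping peak score when no track."""
    out: dict[str, float] = {}
    trees = peaks.index() if peaks is not None else {}
    for g in genes:
        promoter = promoter_interval(g, upstream, downstream)
        if track is not None:
            out[g.gene_id] = track.mean_over(promoter.chrom, promoter.start, promoter.end)
        elif peaks is not None:
            tree = trees.get(promoter.chrom)
            hits = tree.overlap(promoter.start, promoter.end) if tree is not None else set()
            out[g.gene_id] = max((h.data.score for h in hits), default=0.0)
        else:
            raise ValueError("promoter_signal needs a signal track or a peak set")
    return out


# ---------------------------------------------------------------------------
# I/O


def read_peaks_bed(path: str | Path) -> PeakSet:
    peaks = []
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
                name = fields[3] if len(fields) > 3 else ""
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                peaks.append(Peak(fields[0], int(fields[1]), int(fields[2]), score, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(peaks)


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks.peaks):
            name = p.name or f"peak{i}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score:g}\n")


def read_bedgraph(
    path: str | Path, chrom_lengths: Mapping[str, int] | None = None
) -> SignalTrack:
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                intervals.setdefault(fields[0], []).append(
                    (int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return SignalTrack(intervals, chrom_lengths)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts = track._starts[chrom]
            ends = track._ends[chrom]
            values = track._values[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_classes_tsv(classes: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\n")
        for g in sorted(classes):
            fh.write(f"{g}\t{classes[g]}\n")
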