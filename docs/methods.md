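# Methods

## The enrichment model

The caller operates on a four-condition immunoprecipitation design: two
wild-type pulldown replicates, a binding-dead point-mutant pulldown and an
empty-vector pulldown, each paired with an input taken from the same lysate.
Expression is log₂(RPKM + pc) over a merged gene-level transcriptome, the
enrichment score is the pulldown-minus-input difference of that quantity per
condition, and the call is

  enriched ⇔ min(WT scores) > 0 ∧ min(WT scores) > max(control scores),

strict on both inequalities. Three interpretation choices are deliberate:

- **Score = difference of log₂ values** (i.e., a log fold change of
  pseudocounted RPKM), not a ratio of logarithms. A ratio of logs is
  scale-pathological (its value depends on the RPKM unit), and the rule's
  "> 0" threshold is meaningful exactly for a log difference.
- **Ties never call.** The rule is conservative on boundaries; with discrete
  counts, exact score ties occur (most commonly at 0 for genes with equal
  pulldown and input counts), and they are counted as not enriched.
- **Genes with zero counts everywhere are retained** with score 0 and
  enriched = false, keeping the gene universe fixed for the overlap stage.

Under the null (no binding, all four condition scores of a gene
exchangeable), P(call) ≤ C(2,2)/C(4,2) = 1/6, since both WT scores must
exceed both control scores; the > 0 clause lowers this further. The test
suite verifies the bound by Monte-Carlo and checks the realized call rate
against exact enumeration of the six equally likely WT/control assignments
per gene (the conditional permutation distribution, which preserves
within-gene tie structure).

## Transcriptome assembly

Transcripts sharing a gene symbol (same chromosome and strand) merge into a
single gene; unsymboled transcripts (e.g., lincRNA predictions) cluster by
single-linkage *exonic* overlap on the same strand, and are never merged into
symboled genes — a cluster spanning multiple annotation sources is logged.
Gene TSS is the most 5′ member-transcript start with respect to strand, so
the promoter window covers the dominant initiation site. Gene ids are the
symbol where available, otherwise `LOCUS_<chrom>_<start>_<strand>`, which
makes assembly deterministic and order-insensitive. All coordinates are
0-based half-open internally; GTF (1-based inclusive) is converted at the
reader boundary, so the promoter arithmetic has a single convention.

## Counting and quantification

A read is assigned to the gene whose exon union contains its midpoint;
strand-agnostic, because library strandedness is not part of the design
contract. If several exon unions contain the midpoint, the gene with the
smaller exonic length wins (specific beats containing), ties break by gene
id, and every ambiguous event is tallied and logged. Spliced-read
exon-junction apportioning, duplicate marking and mapping-quality filters are
out of scope — the pipeline starts from mapped-read intervals or counts.
The RPKM denominator is the per-sample total mapped reads supplied with the
sample sheet, not the column sum, matching how sequencing depth is usually
reported. The pseudocount (default 1.0, recorded in output metadata) bounds
log₂ RPKM below by 0 for silent genes; because RPKM is depth-invariant, the
pseudocount's damping strength depends on the RPKM scale of the experiment,
which is why it is configurable.

## ChIP overlap, quintiles, metagenes

Promoter = [TSS − 2000, TSS + 1000) on the + strand, mirrored on −, clipped
at position 0; bound = ≥ 1 bp intersection with any peak under half-open
coordinates (abutting intervals do not overlap). The Fisher p-value is
computed with exact integer arithmetic: one-sided "greater" is the upper
hypergeometric tail; two-sided sums all outcomes whose probability does not
exceed the observed one, compared as exact integers so ties are handled
without a floating-point epsilon. The odds ratio is the sample cross-product
ratio (∞ when only one off-diagonal cell is 0, NaN for 0/0). The universe
for the 2×2 table is the assembled transcriptome.

Top quintile = the ⌈n/5⌉ bound promoters with the highest mean track signal
over the promoter window (max overlapping peak score when no track is
supplied); boundary ties resolve by gene id and are logged.

Metagene profiles average the signal in 100 equal bins over TSS ± 5 kb,
reversing bin order for − strand genes so bin 1 is always 5′. Bin means are
computed exactly from the piecewise-constant track (interval integrals, not
sampling). A bin that extends beyond its chromosome is missing for that gene
and excluded from that bin's cross-gene mean; a window's uncovered interior
counts as signal 0.

## The synthetic-data generator

The generator emulates the study at roughly 1/100 sequencing scale so the
full pipeline runs in seconds: by default 2000 genes (1–5 exons of
100–800 bp) on four 5 Mb chromosomes, 5 × 10⁵ expected reads per sample
against the tens of millions of mapped reads per library of a real
experiment, 5% planted binders with a log₂ pulldown effect of 3, and an
optional leak term for residual control enrichment (default 0).

Counts follow a gamma–Poisson (negative binomial) model with one structural
commitment: **each condition is one lysate**. A per-condition gamma
fluctuation (dispersion parameter, default 0.1 — the scale of biological
replicate variability in sequencing count data) multiplies the log-normal
baseline (ln-sd 1.2, a realistic expression spread) and is *shared* between
the condition's pulldown and its matched input. That is what a matched input
is for: abundance noise common to the lysate cancels in the enrichment
score, leaving Poisson shot noise. Marginally every sample is still
NB(mean, dispersion). Pulldown means multiply the lysate abundance by
2^effect and are renormalised per sample, so strong binders deplete the rest
of the pulldown library — the compositional behaviour of real
immunoprecipitation (at the defaults this shifts non-binder WT scores by
about −log₂(1 + 0.05·7) ≈ −0.43, visible in recovered effect sizes).

Library sizes are realized as column sums inflated by the configured
unassigned fraction (default 5%); `equal_library_sizes` instead fixes every
denominator at the nominal depth, giving an exactly-identical-depths design.
The distinction matters for null calibration: with realized depths, small
sample-level depth fluctuations shift all of a sample's scores coherently,
so the four condition scores of a gene are exchangeable only approximately,
and the strict > 0 clause sits on score atoms at low counts. Identical
denominators restore exact exchangeability, which is the regime in which the
1/6 bound and the permutation oracle are sharp.

The ChIP layer places peaks (default 600 bp) at a configurable fraction of
TSSs — optionally a higher fraction among binders, to populate the "both"
class — over a constant background (0.5) with Gaussian bumps (height ~10,
piecewise-constant at 25 bp resolution) at peaked promoters.

**What passing tests show, and what they do not.** The generator has no
alignment error, no fragment or crosslinking bias, no spliced reads, no
IP-efficiency variation per gene between experiments, and its matched-pair
model makes enrichment scores shot-noise-limited at high counts. Recovery
numbers (sensitivity ≈ 0.99, specificity ≈ 0.99 at the defaults) therefore
characterise the calling rule under its own model assumptions, not expected
performance on real libraries, where replicate IP variability adds score
noise the negative-control design only partially absorbs.

## Numerical and degenerate-input choices

- Fisher p-values: exact integers throughout; agreement with enumeration is
  exact, and with scipy's implementation to ~1e-7 relative (scipy's
  two-sided tie comparison uses a small relative epsilon).
- Midpoint of a length-ℓ read is start + ⌊ℓ/2⌋.
- Empty annotation files parse to an empty list with a warning; malformed
  lines raise errors naming the line number; exon blocks outside a
  transcript span reject that record with a warning.
- Zero-gene or zero-read inputs produce empty-but-valid outputs; an empty
  gene universe for the overlap test is an error.
- All simulation stages draw from independent, crc32-keyed child streams of
  the single seed, so adding a stage never perturbs another stage's draws,
  and outputs are byte-identical across runs and processes.

## Problem sizes

Defaults were chosen so that a full study — simulation, assembly, counting,
calling, overlap, metagenes — completes in seconds, and the complete test
suite (including a 10⁵-gene null simulation, a 20-replicate recovery
benchmark and exhaustive Fisher enumeration over all universes ≤ 60) in
well under a minute on one core.

## Known limitations

- The grouping of unsymboled transcripts (single-linkage exonic overlap) is
  one defensible convention among several; annotation sources that disagree
  on symbols will produce different gene universes.
- Multi-mapped reads are invisible to the midpoint rule (each interval is
  counted once); no per-transcript quantification is attempted.
- Hierarchical clustering/heatmap rendering of the enrichment matrix is out
  of scope; the score matrix is exported for external tools.
- The Fisher universe, the quintile ranking signal and the metagene window
  are configurable because none of them has a single canonical definition;
  changing them changes the overlap numbers, and the manifest records the
  values used.
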