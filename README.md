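# ripitseq

A tested, reusable implementation of negative-control-based RIP/RIPiT-seq
differential enrichment calling, with the downstream promoter-overlap and
metagene analyses that relate protein-bound RNAs to the protein's chromatin
occupancy. It is aimed at analysts working with tandem-immunoprecipitation
sequencing designs of the form *WT pulldown (duplicate) vs binding-dead
mutant vs empty vector*, each with a matched input — and at anyone who wants
a fully ground-truthed synthetic testbed for such designs.

## The method

Transcripts from one or more annotation sources (BED12, GTF) are merged into
a non-redundant, strand-aware gene-level transcriptome; each gene carries an
exon union of length *L* and a TSS. Per sample, reads are counted by a
midpoint-in-exon-union rule and expression is quantified as

    RPKM = C · 10⁹ / (N · L),        x = log₂(RPKM + pc)

with read count *C*, total mapped reads *N* and pseudocount *pc* (default 1).
The **enrichment score** of gene *g* in condition *c* is the difference of
pseudocounted log₂ RPKM between the pulldown and its matched input,

    s_gc = x_g,pulldown(c) − x_g,input(c)

and a gene is called **enriched** when

    min(s_g,WT1, s_g,WT2) > 0   and   min(s_g,WT1, s_g,WT2) > max(s_g,mut, s_g,vec)

with strict inequalities (ties never call). The rule is deterministic; under
score exchangeability (no true binding) its false-call probability is bounded
by C(2,2)/C(4,2) = 1/6, and the >0 clause lowers it further.

Downstream, a gene is **ChIP-bound** when its promoter window (2 kb upstream
to 1 kb downstream of the TSS, strand-aware, half-open coordinates) overlaps
any ChIP peak by ≥ 1 bp. The ChIP-bound × RIP-enriched overlap over the full
gene universe is tested with Fisher's exact test (exact hypergeometric
p-value, one-sided "greater" by default), genes are classified as
both / chip_only / rip_only / neither, the overlap is repeated on the top
quintile of bound promoters ranked by mean signal, and per-class metagene
profiles average the ChIP signal in 100 bins over TSS ± 5 kb, strand-oriented.

A synthetic-data module generates the whole study at desk scale — genome,
gene models, negative-binomial counts for the 4 × 2 design with a planted
binder set, ChIP peaks and signal — with full ground truth and byte-level
determinism from a single seed.

## Worked example

The numbered scripts under `analysis/` run the study end to end on synthetic
data (all outputs under `results/`):

```bash
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_assemble_and_quantify.py
python analysis/03_call_enriched_genes.py
python analysis/04_chip_overlap_classification.py
python analysis/05_metagene_profiles.py
python analysis/06_recovery_benchmark.py
```

which prints, for seed 1:

```
simulated 2000 genes on 4 chromosomes (5 Mb each), depth 500000 reads/sample
planted binders: 100  peaked promoters: 553
113 of 2000 genes called WT-enriched
recovery vs truth: sensitivity 0.990, specificity 0.9926
60 of 568 ChIP-bound genes also have RIP signal (universe 2000, odds ratio 3.07, Fisher p = 1.11e-08)
top quintile: 9 of 114 bound promoters produce an enriched RNA
      both:   60 genes, TSS-bin signal 9.69
 chip_only:  508 genes, TSS-bin signal 9.60
  rip_only:   53 genes, TSS-bin signal 0.50
20 replicates: mean sensitivity 0.9955, mean specificity 0.9947
null (no effect) call rate over 50000 genes: 0.0825 (exchangeability bound 1/6 = 0.1667)
```

Read: the caller recovers 99 of the 100 planted binders with ~7 false
positives in 1900 null genes; ChIP-bound genes whose RNA is also enriched
("both") have metagene profiles indistinguishable from chip_only genes,
while rip_only genes sit at the background level — the signature that
distinguishes candidate *cis*-acting RNAs from RNAs bound away from their
own locus.

The same pipeline runs as a CLI (`ripitseq simulate|assemble|count|quantify|
call|overlap|metagene|run-all`) on user-supplied BED12/GTF annotations,
BED6 reads or count tables, BED peaks and bedGraph signal; `run-all` takes a
YAML config and writes a manifest with parameters and output checksums.

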