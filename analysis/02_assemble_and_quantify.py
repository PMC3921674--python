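#!/usr/bin/env python
"""Assemble the non-redundant transcriptome and quantify log2 RPKM.

Reads the annotation written by 01_simulate_dataset.py (or any BED12),
merges transcripts into gene models, loads the count table, and writes the
gene table and the log2(RPKM + 1) expression matrix under results/.
"""

import argparse
from pathlib import Path

from ripitseq.annotation import assemble_transcriptome, read_bed12, write_gene_table
from ripitseq.quantify import build_expression_matrix, read_counts_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--pseudocount", type=float, default=1.0)
    args = ap.parse_args()

    genes = assemble_transcriptome(read_bed12(args.datadir / "annotation.bed12", "sim"))
    table = read_counts_tsv(args.datadir / "counts.tsv", args.datadir / "samples.tsv")
    order = {g.gene_id: g for g in genes}
    expr = build_expression_matrix(
        table, [order[g] for g in table.genes], args.pseudocount
    )

    args.outdir.mkdir(parents=True, exist_ok=True)
    write_gene_table(genes, args.outdir / "gene_table.tsv")
    expr.to_frame().to_csv(args.outdir / "expression.tsv", sep="\t")
    print(f"assembled {len(genes)} genes; "
          f"expression matrix {len(expr.genes)} x {len(expr.sample_ids)} "
          f"(pseudocount {args.pseudocount})")


if __name__ == "__main__":
    main()
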