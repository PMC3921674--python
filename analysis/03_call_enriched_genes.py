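#!/usr/bin/env python
"""Call WT-enriched RNAs by the replicate-and-negative-control rule.

A gene is enriched when its minimum enrichment score (pulldown minus input
log2 RPKM) across both WT replicates is greater than 0 and greater than the
maximum score in the F266A and empty-vector controls.  Writes the per-gene
score/call table, the enriched gene list, and a clustering-friendly score
matrix under results/, and reports recovery against the simulation truth
when it is available.
"""

import argparse
from pathlib import Path

import pandas as pd

from ripitseq.enrichment import (
    call_all,
    write_enriched_list,
    write_enrichment_tsv,
    write_score_matrix,
)
from ripitseq.quantify import ExpressionMatrix, read_sample_sheet
from ripitseq.simulate import SimTruth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.outdir / "expression.tsv", sep="\t", index_col=0)
    samples = read_sample_sheet(args.datadir / "samples.tsv")
    expr = ExpressionMatrix(
        genes=list(df.index), sample_ids=list(df.columns),
        values=df.to_numpy(), pseudocount=1.0,
    )
    _, frame = call_all(expr, samples)
    write_enrichment_tsv(frame, args.outdir / "enrichment.tsv")
    write_enriched_list(frame, args.outdir / "enriched_genes.txt")
    write_score_matrix(frame, args.outdir / "score_matrix.tsv")
    n = int(frame["enriched"].sum())
    print(f"{n} of {len(frame)} genes called WT-enriched")

    truth_path = args.datadir / "truth.json"
    if truth_path.exists():
        truth = SimTruth.from_json(truth_path)
        called = set(frame.index[frame["enriched"]])
        binders = set(truth.binders)
        others = set(frame.index) - binders
        print(f"recovery vs truth: sensitivity "
              f"{len(called & binders) / len(binders):.3f}, specificity "
              f"{len(others - called) / len(others):.4f}")


if __name__ == "__main__":
    main()
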