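#!/usr/bin/env python
"""Relate RIP-enriched RNAs to promoter ChIP occupancy.

Defines ChIP-bound genes (promoter window 2 kb upstream / 1 kb downstream of
the TSS overlapping any peak), tests the overlap with the enriched RNA set by
Fisher's exact test, classifies every gene (both / chip_only / rip_only /
neither), and repeats the overlap restricted to the top quintile of bound
promoters ranked by mean signal.  Writes overlap.json and classes.tsv under
results/.
"""

import argparse
import json
from pathlib import Path

from ripitseq.annotation import assemble_transcriptome, read_bed12
from ripitseq.chip import (
    chip_bound_genes,
    fisher_overlap,
    promoter_signal,
    read_bedgraph,
    read_peaks_bed,
    top_quintile_promoters,
    write_classes_tsv,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--alternative", choices=["greater", "two-sided"], default="greater")
    args = ap.parse_args()

    genes = assemble_transcriptome(read_bed12(args.datadir / "annotation.bed12", "sim"))
    peaks = read_peaks_bed(args.datadir / "peaks.bed")
    track = read_bedgraph(args.datadir / "signal.bedgraph")
    rip = {l.strip() for l in open(args.outdir / "enriched_genes.txt") if l.strip()}

    universe = {g.gene_id for g in genes}
    chip = chip_bound_genes(genes, peaks)
    res = fisher_overlap(universe, chip, rip & universe, args.alternative)
    write_classes_tsv(res.classes, args.outdir / "classes.tsv")

    by_id = {g.gene_id: g for g in genes}
    signal = promoter_signal([by_id[g] for g in sorted(chip)], track)
    top = top_quintile_promoters(signal)
    top_res = fisher_overlap(universe, top, rip & universe, args.alternative)

    summary = {
        "universe_size": res.universe_size,
        "n_chip_bound": res.n_chip,
        "n_rip_enriched": res.n_rip,
        "n_both": res.n_both,
        "odds_ratio": res.odds_ratio,
        "p_value": res.p_value,
        "class_counts": res.class_counts(),
        "top_quintile": {
            "n_top": top_res.n_chip,
            "n_both": top_res.n_both,
            "p_value": top_res.p_value,
        },
    }
    with open(args.outdir / "overlap.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(f"{res.n_both} of {res.n_chip} ChIP-bound genes also have RIP signal "
          f"(universe {res.universe_size}, odds ratio {res.odds_ratio:.2f}, "
          f"Fisher p = {res.p_value:.3g})")
    print(f"top quintile: {top_res.n_both} of {top_res.n_chip} bound promoters "
          f"produce an enriched RNA")


if __name__ == "__main__":
    main()
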