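#!/usr/bin/env python
"""Metagene profiles of ChIP signal for each RIP/ChIP gene class.

Averages the signal track in 100 bins across a TSS-centred, strand-oriented
+/-5 kb window, separately for the both / chip_only / rip_only / neither
classes.  Writes one TSV per class under results/ and a combined figure under
results/figures/.
"""

import argparse
from pathlib import Path

import pandas as pd

from ripitseq.annotation import assemble_transcriptome, read_bed12
from ripitseq.chip import CLASS_LABELS, metagene_profile, read_bedgraph


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--window", type=int, default=5000)
    ap.add_argument("--bins", type=int, default=100)
    args = ap.parse_args()

    genes = assemble_transcriptome(read_bed12(args.datadir / "annotation.bed12", "sim"))
    track = read_bedgraph(args.datadir / "signal.bedgraph")
    classes = pd.read_csv(args.outdir / "classes.tsv", sep="\t", index_col=0)["class"]
    by_id = {g.gene_id: g for g in genes}

    profiles = {}
    for label in CLASS_LABELS:
        members = sorted(classes.index[classes == label])
        prof = metagene_profile(
            track, [by_id[g] for g in members], args.window, args.bins, label
        )
        prof.to_frame().to_csv(args.outdir / f"metagene_{label}.tsv", sep="\t",
                               index=False)
        profiles[label] = prof
        center = prof.mean_signal[args.bins // 2]
        print(f"{label:>10}: {prof.n_genes:4d} genes, TSS-bin signal {center:.2f}")

    figdir = args.outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label in ("both", "chip_only", "rip_only"):
        prof = profiles[label]
        ax.plot(prof.bin_centers, prof.mean_signal,
                label=f"{label} (n={prof.n_genes})")
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel("mean ChIP signal")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(figdir / "metagene_classes.png", dpi=150)
    print(f"figure written to {figdir / 'metagene_classes.png'}")


if __name__ == "__main__":
    main()
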