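"""Per-sample enrichment scores and the replicate-and-negative-control call.

The enrichment score of a gene in a condition is the difference of
log2(RPKM + pseudocount) between the pulldown sample and its matched input.
A gene is called enriched in the wild-type pulldown when the minimum score
across both WT replicates is strictly greater than 0 and strictly greater
than the maximum score across the two negative controls (the RNA-binding-dead
F266A mutant and the empty-vector pulldown).  Ties therefore never call; the
rule is deterministic and carries no p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix, Sample

WT_CONDITIONS = ("WT_rep1", "WT_rep2")
CONTROL_CONDITIONS = ("F266A", "vector")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-gene scores, the WT-enriched call, and its audit trail."""

    gene_id: str
    scores: dict  # condition -> enrichment score
    wt_min: float
    ctrl_max: float
    enriched: bool


def enrichment_score(log2_pulldown: float, log2_input: float) -> float:
    """Log2 fold change of pseudocounted RPKM: pulldown minus matched input."""
    return log2_pulldown - log2_input


def call_enriched(
    wt_scores: Sequence[float], control_scores: Sequence[float]
) -> tuple[bool, float, float]:
    """Apply the replicate-and-negative-control rule to one gene.

    Returns ``(enriched, wt_min, ctrl_max)`` where ``enriched`` is
    ``min(wt) > 0 and min(wt) > max(controls)`` with strict inequalities.
    """
    if len(wt_scores) < 2:
        raise ValueError("the design requires at least 2 wild-type replicate scores")
    if len(control_scores) < 1:
        raise ValueError("the design requires at least 1 negative-control score")
    wt_min = float(min(wt_scores))
    ctrl_max = float(max(control_scores))
    return (wt_min > 0.0) and (wt_min > ctrl_max), wt_min, ctrl_max


def score_matrix(expr: ExpressionMatrix, samples: Sequence[Sample]) -> pd.DataFrame:
    """Gene x condition matrix of pulldown-minus-input enrichment scores."""
    pulldowns = {s.condition: s for s in samples if s.role == "pulldown"}
    required = WT_CONDITIONS + CONTROL_CONDITIONS
    missing = [c for c in required if c not in pulldowns]
    if missing:
        raise ValueError(f"sample sheet lacks pulldown samples for conditions: {missing}")
    cols = {}
    for cond in required:
        pd_sample = pulldowns[cond]
        if pd_sample.paired_input_id not in expr.sample_ids:
            raise ValueError(
                f"pulldown {pd_sample.sample_id}: paired input "
                f"{pd_sample.paired_input_id!r} missing from expression matrix"
            )
        cols[cond] = expr.column(pd_sample.sample_id) - expr.column(pd_sample.paired_input_id)
    return pd.DataFrame(cols, index=expr.genes)


def call_all(
    expr: ExpressionMatrix, samples: Sequence[Sample]
) -> tuple[list[EnrichmentResult], pd.DataFrame]:
    """Score every gene in every condition and call the WT-enriched set.

    Returns the per-gene results and a table with one row per gene:
    the four condition scores, wt_min, ctrl_max and the boolean call.
    """
    scores = score_matrix(expr, samples)
    wt = scores[list(WT_CONDITIONS)].to_numpy()
    ctrl = scores[list(CONTROL_CONDITIONS)].to_numpy()
    wt_min = wt.min(axis=1)
    ctrl_max = ctrl.max(axis=1)
    enriched = (wt_min > 0.0) & (wt_min > ctrl_max)

    frame = scores.copy()
    frame.columns = [f"score_{c}" for c in scores.columns]
    frame["wt_min"] = wt_min
    frame["ctrl_max"] = ctrl_max
    frame["enriched"] = enriched
    frame.index.name = "gene_id"

    results = [
        EnrichmentResult(
            gene_id=g,
            scores={c: float(scores.at[g, c]) for c in scores.columns},
            wt_min=float(wt_min[i]),
            ctrl_max=float(ctrl_max[i]),
            enriched=bool(enriched[i]),
        )
        for i, g in enumerate(scores.index)
    ]
    return results, frame


def enriched_gene_set(results: Sequence[EnrichmentResult]) -> set[str]:
    return {r.gene_id for r in results if r.enriched}


def write_enrichment_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t")


def write_enriched_list(frame: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in frame.index[frame["enriched"]]:
            fh.write(f"{gene}\n")


def write_score_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    """Score matrix alone (genes x conditions) for external clustering tools."""
    cols = [c for c in frame.columns if c.startswith("score_")]
    frame[cols].to_csv(path, sep="\t")
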