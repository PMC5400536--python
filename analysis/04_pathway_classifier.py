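#!/usr/bin/env python
"""Pathway deviation scores and two-circle risk-pathway ranking.

Reads results/cohort/ and results/<tissue>_degs.tsv; writes
results/<tissue>_pathway_scores.tsv (per-sample U/D) and
results/<tissue>_pathway_eval.tsv (precisions, risk flag).
"""

import argparse
from pathlib import Path

import pandas as pd

from riskpath.center_classifier import (
    evaluate_score_matrix,
    evaluations_frame,
    rank_pathways,
)
from riskpath.io_preprocess import read_expression, zscore_normalize
from riskpath.pathway_deviation import read_gmt, score_matrix


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()
    cohort_dir = args.results / "cohort"
    gene_sets = read_gmt(cohort_dir / "pathways.gmt")

    for tissue in ("tumor", "normal"):
        m = read_expression(
            cohort_dir / f"expression_{tissue}.tsv",
            cohort_dir / f"annotation_{tissue}.tsv",
        )
        z = zscore_normalize(m)
        degs = pd.read_csv(
            args.results / f"{tissue}_degs.tsv", sep="\t", index_col="gene_id"
        )
        degs = degs[degs["q_value"] < 0.05]

        scores = score_matrix(z, gene_sets, degs)
        _, _, evals = evaluate_score_matrix(scores, z.groups, 0.8)
        ranked = rank_pathways(evals, threshold=0.65, top_k=4)
        risk_ids = [e.pathway_id for e in ranked]

        scores.to_long().set_index("sample_id").to_csv(
            args.results / f"{tissue}_pathway_scores.tsv", sep="\t",
            float_format="%.10g",
        )
        frame = evaluations_frame(evals, risk_ids)
        out = args.results / f"{tissue}_pathway_eval.tsv"
        frame.to_csv(out, sep="\t", float_format="%.10g")
        shown = ", ".join(
            f"{e.pathway_id} ({e.mean_precision:.3f})" for e in ranked
        )
        print(f"{tissue}: risk pathways {shown} -> {out}")


if __name__ == "__main__":
    main()
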