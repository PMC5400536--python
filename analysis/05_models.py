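#!/usr/bin/env python
"""Cross-validated random-forest classification on risk-pathway features.

Reads results/<tissue>_pathway_scores.tsv and results/<tissue>_pathway_eval.tsv;
writes results/model_performance.tsv (per-fold and mean AUC/accuracy).
"""

import argparse
from pathlib import Path

import pandas as pd

from riskpath.io_preprocess import read_expression
from riskpath.models import FeatureTable, cross_validate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()
    cohort_dir = args.results / "cohort"

    rows = []
    for tissue in ("tumor", "normal"):
        m = read_expression(
            cohort_dir / f"expression_{tissue}.tsv",
            cohort_dir / f"annotation_{tissue}.tsv",
        )
        evals = pd.read_csv(
            args.results / f"{tissue}_pathway_eval.tsv", sep="\t",
            index_col="pathway_id",
        )
        risk_ids = evals.index[evals["risk_flag"]].tolist()
        # highest mean precision first, the feature column order
        risk_ids = sorted(
            risk_ids, key=lambda p: -evals.loc[p, "mean_precision"]
        )
        long = pd.read_csv(args.results / f"{tissue}_pathway_scores.tsv", sep="\t")
        u = long.pivot(index="sample_id", columns="pathway_id", values="U")
        cols = {}
        for pid in risk_ids:
            cols[f"{pid}|U"] = u[pid]
            cols[f"{pid}|D"] = long.pivot(
                index="sample_id", columns="pathway_id", values="D"
            )[pid]
        x = pd.DataFrame(cols).loc[list(m.sample_ids)]
        features = FeatureTable(x, pd.Series(dict(m.groups)).loc[x.index])

        for model in ("random_forest", "svm"):
            cv = cross_validate(features, model=model, folds=5, seed=args.seed)
            rows.append(
                {
                    "tissue": tissue,
                    "model": model,
                    "mean_auc": cv.mean_auc,
                    "mean_accuracy": cv.mean_accuracy,
                    **{f"fold{i}_auc": f.auc for i, f in enumerate(cv.folds)},
                }
            )
            print(
                f"{tissue} {model}: mean AUC {cv.mean_auc:.3f}, "
                f"mean accuracy {cv.mean_accuracy:.3f}"
            )

    out = args.results / "model_performance.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format="%.10g")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
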