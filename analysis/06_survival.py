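#!/usr/bin/env python
"""Survival screening of risk genes and altered-vs-unaltered KM comparisons.

Per tissue: risk genes = risk-pathway members that are DEGs; each is screened
by its single-gene log-rank test, and the kept set stratifies patients into
altered/unaltered.  The two tissues' kept sets are then integrated by union.
Writes results/survival_summary.tsv and results/integrated_risk_genes.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from riskpath.deg_exceedance import reference_intervals
from riskpath.io_preprocess import read_expression, zscore_normalize
from riskpath.pathway_deviation import read_gmt
from riskpath.survival import (
    integrate_gene_sets,
    km_logrank,
    mark_altered,
    screen_genes,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()
    cohort_dir = args.results / "cohort"
    gene_sets = read_gmt(cohort_dir / "pathways.gmt")
    surv = pd.read_csv(cohort_dir / "clinical.tsv", sep="\t", index_col="sample_id")

    rows = []
    state = {}
    for tissue in ("tumor", "normal"):
        m = read_expression(
            cohort_dir / f"expression_{tissue}.tsv",
            cohort_dir / f"annotation_{tissue}.tsv",
        )
        z = zscore_normalize(m)
        degs = pd.read_csv(
            args.results / f"{tissue}_degs.tsv", sep="\t", index_col="gene_id"
        )
        deg_ids = set(degs.index[degs["q_value"] < 0.05])
        evals = pd.read_csv(
            args.results / f"{tissue}_pathway_eval.tsv", sep="\t",
            index_col="pathway_id",
        )
        risk_ids = evals.index[evals["risk_flag"]].tolist()
        members = {g for pid in risk_ids for g in gene_sets[pid].genes}
        risk_genes = sorted(members & deg_ids)

        intervals = reference_intervals(z)
        kept = screen_genes(risk_genes, z, intervals, surv)
        state[tissue] = (z, intervals, kept)
        table = surv.copy()
        table["altered"] = mark_altered(z, kept, intervals)
        km = km_logrank(table)
        rows.append(
            {
                "analysis": tissue,
                "n_risk_genes": len(risk_genes),
                "n_screened": len(kept),
                "n_altered": km.group_sizes["altered"],
                "logrank_statistic": km.statistic,
                "logrank_p": km.p_value,
            }
        )
        print(
            f"{tissue}: {len(kept)}/{len(risk_genes)} genes kept, "
            f"log-rank p = {km.p_value:.3g}"
        )

    tagged = integrate_gene_sets(state["tumor"][2], state["normal"][2])
    tagged.rename_axis("gene_id").to_csv(
        args.results / "integrated_risk_genes.tsv", sep="\t"
    )
    flags = None
    for tissue, (z, intervals, kept) in state.items():
        f = mark_altered(z, sorted(kept), intervals)
        flags = f if flags is None else (flags | f)
    table = surv.copy()
    table["altered"] = flags
    km = km_logrank(table)
    rows.append(
        {
            "analysis": "integrated",
            "n_risk_genes": len(tagged),
            "n_screened": len(tagged),
            "n_altered": km.group_sizes["altered"],
            "logrank_statistic": km.statistic,
            "logrank_p": km.p_value,
        }
    )
    print(f"integrated: {len(tagged)} genes, log-rank p = {km.p_value:.3g}")

    out = args.results / "survival_summary.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format="%.10g")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
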