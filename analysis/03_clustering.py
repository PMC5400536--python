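#!/usr/bin/env python
"""Hierarchical clustering on DEGs and at-risk good-subgroup identification.

Reads results/cohort/ and results/<tissue>_degs.tsv; writes
results/<tissue>_clusters.tsv (cluster id, subgroup id, at-risk flag).
"""

import argparse
from pathlib import Path

import pandas as pd

from riskpath.clustering import (
    cluster_purity,
    cluster_samples,
    cut_to_clusters,
    identify_at_risk,
    subgroup_assignment,
)
from riskpath.io_preprocess import (
    filter_for_clustering,
    median_center,
    read_expression,
    zscore_normalize,
)

K_CLUSTERS = {"tumor": 3, "normal": 4}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()
    cohort_dir = args.results / "cohort"

    for tissue in ("tumor", "normal"):
        m = read_expression(
            cohort_dir / f"expression_{tissue}.tsv",
            cohort_dir / f"annotation_{tissue}.tsv",
        )
        degs = pd.read_csv(
            args.results / f"{tissue}_degs.tsv", sep="\t", index_col="gene_id"
        )
        deg_ids = list(degs.index[degs["q_value"] < 0.05])

        centered = median_center(filter_for_clustering(m))
        cluster_genes = [g for g in deg_ids if g in centered.values.index]
        tree = cluster_samples(centered, cluster_genes)
        assignment = cut_to_clusters(tree, K_CLUSTERS[tissue])
        purity = cluster_purity(assignment, zscore_normalize(m).groups)
        at_risk = identify_at_risk(centered, assignment, cluster_genes)
        table = subgroup_assignment(assignment, m.groups, at_risk)

        out = args.results / f"{tissue}_clusters.tsv"
        table.to_csv(out, sep="\t")
        print(
            f"{tissue}: poor recall {purity.attrs['poor_recall']:.3f}, "
            f"{len(at_risk)} at-risk good samples {sorted(at_risk)} -> {out}"
        )


if __name__ == "__main__":
    main()
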