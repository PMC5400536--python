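#!/usr/bin/env python
"""Per-tissue exceedance DEG tables (permutation p-values, BH q-values).

Reads results/cohort/, writes results/<tissue>_degs.tsv.
"""

import argparse
from pathlib import Path

from riskpath.deg_exceedance import deg_table
from riskpath.io_preprocess import read_expression, zscore_normalize


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-perm", type=int, default=10000)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()
    cohort_dir = args.results / "cohort"

    for tissue in ("tumor", "normal"):
        m = read_expression(
            cohort_dir / f"expression_{tissue}.tsv",
            cohort_dir / f"annotation_{tissue}.tsv",
        )
        table = deg_table(
            zscore_normalize(m), alpha=0.05, n_perm=args.n_perm, seed=args.seed
        )
        out = args.results / f"{tissue}_degs.tsv"
        table.to_csv(out, sep="\t", float_format="%.10g")
        called = table[table["q_value"] < 0.05]
        print(
            f"{tissue}: {len(called)} DEGs at q<0.05 "
            f"({(called['direction'] == 'up').sum()} up, "
            f"{(called['direction'] == 'down').sum()} down) -> {out}"
        )


if __name__ == "__main__":
    main()
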