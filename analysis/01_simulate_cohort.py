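#!/usr/bin/env python
"""Generate the default paired tumor/normal synthetic cohort.

Writes expression/annotation TSVs, pathways.gmt, clinical.tsv and truth.json
under results/cohort/.
"""

import argparse
from pathlib import Path

from riskpath.synthetic_data import SimulationConfig, generate, write_fixture


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = generate(SimulationConfig(seed=args.seed))
    paths = write_fixture(cohort, args.results / "cohort")
    for name, p in sorted(paths.items()):
        print(f"{name}: {p}")


if __name__ == "__main__":
    main()
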