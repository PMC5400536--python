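"""Per-sample pathway deviation scores from up- and down-regulated DEGs.

A dysfunctional pathway shows up not only as individual gene shifts but as a
loss of balance across its members.  For a pathway with up-regulated DEG
members ``up`` (|up| = N1) and down-regulated members ``down`` (|down| = N2),
a sample with expression x_g and good-group gene means mu_g gets the score
vector T = (U, D):

    U = sum_{g in up}   (x_g - mu_g)^3 / N1
    D = sum_{g in down} (x_g - mu_g)^3 / N2

Cubing keeps the deviation sign while amplifying large excursions, so a
sample whose up-DEGs sit far above their normal means gets a large positive
U.  Empty member sets score 0 by convention.  N1/N2 are pathway-member DEG
counts, not cohort sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    id: str
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has no member genes")


@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets (GMT semantics; members are sets)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate pathway id: {dup!r}")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, pathway_id: str) -> GeneSet:
        for s in self.sets:
            if s.id == pathway_id:
                return s
        raise KeyError(pathway_id)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sets]


def read_gmt(path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file (id, description, members...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            pid, name, *members = fields
            members = [g for g in members if g]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning(
                    "%s: line %d: duplicate member gene(s) in %s deduplicated",
                    path, lineno, pid,
                )
            sets.append(GeneSet(pid, name, tuple(deduped)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.id, s.name, *s.genes]) + "\n")


def deviation_vector(
    sample_values, up_genes, down_genes, good_means
) -> tuple[float, float]:
    """(U, D) for one sample from explicit up/down member gene sets.

    ``sample_values`` and ``good_means`` map gene id -> value; a member gene
    missing from either is a hard error naming the gene.
    """

    def _mean_cubed(genes) -> float:
        genes = sorted(genes)
        if not genes:
            return 0.0
        total = 0.0
        for g in genes:
            if g not in sample_values:
                raise KeyError(f"gene {g!r} missing from sample values")
            if g not in good_means:
                raise KeyError(f"gene {g!r} missing from good-group means")
            total += (sample_values[g] - good_means[g]) ** 3
        return total / len(genes)

    return _mean_cubed(up_genes), _mean_cubed(down_genes)


@dataclass
class ScoreMatrix:
    """Per-sample, per-pathway (U, D) deviation scores (samples x pathways)."""

    u: pd.DataFrame
    d: pd.DataFrame

    def __post_init__(self):
        if not self.u.index.equals(self.d.index) or not self.u.columns.equals(
            self.d.columns
        ):
            raise ValueError("U and D matrices must share samples and pathways")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.u.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.u.columns)

    def points(self, pathway_id: str) -> np.ndarray:
        """(n_samples, 2) array of (U, D) points for one pathway."""
        return np.column_stack(
            [self.u[pathway_id].to_numpy(), self.d[pathway_id].to_numpy()]
        )

    def to_long(self) -> pd.DataFrame:
        long = (
            self.u.stack().rename("U").to_frame().join(self.d.stack().rename("D"))
        )
        long.index.names = ["sample_id", "pathway_id"]
        return long.reset_index()


def score_matrix(
    m: ExpressionMatrix, sets: GeneSetCollection, degs: pd.DataFrame
) -> ScoreMatrix:
    """Score every sample (good and poor) on every pathway.

    ``degs`` is a DEG table with a ``direction`` column (from ``call_degs``);
    per-gene means mu come from the matrix's good-prognosis samples.  Member
    genes absent from the matrix or not DEGs are ignored (logged); a pathway
    with no up (down) DEG members gets an all-zero U (D) column.
    """
    up = set(degs.index[degs["direction"] == "up"])
    down = set(degs.index[degs["direction"] == "down"])
    good = m.samples_in_group("good")
    mu = m.values[good].mean(axis=1)
    dev3 = (m.values.sub(mu, axis=0)) ** 3  # genes x samples

    present = set(m.values.index)
    u_cols, d_cols = {}, {}
    zeros = pd.Series(0.0, index=m.values.columns)
    for s in sets:
        members = set(s.genes)
        absent = members - present
        if absent:
            logger.info(
                "pathway %s: %d member gene(s) absent from matrix, ignored",
                s.id, len(absent),
            )
        up_members = sorted(members & present & up)
        down_members = sorted(members & present & down)
        if not up_members and not down_members:
            logger.warning("pathway %s has no expressed DEG members; scores 0", s.id)
        u_cols[s.id] = dev3.loc[up_members].mean(axis=0) if up_members else zeros
        d_cols[s.id] = dev3.loc[down_members].mean(axis=0) if down_members else zeros

    u = pd.DataFrame(u_cols, index=m.values.columns)[sets.ids]
    d = pd.DataFrame(d_cols, index=m.values.columns)[sets.ids]
    u.index.name = d.index.name = "sample_id"
    return ScoreMatrix(u, d)
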