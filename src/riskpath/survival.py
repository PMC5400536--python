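"""Kaplan–Meier stratification by risk-gene alteration status.

A patient counts as *altered* when the expression of at least one risk gene
falls outside that gene's reference interval (the same mean +/- 1.96 SD
normal range the DEG test uses — an expression-level proxy for alteration
status).  Altered and unaltered patients are compared with the product-limit
estimator and the two-group log-rank test (hypergeometric tie correction).
Genes whose single-gene stratification is not survival-associated can be
screened out, and tumor- and normal-tissue risk-gene sets can be integrated
by union with per-gene provenance tags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


def mark_altered(
    expr: ExpressionMatrix, genes, intervals: pd.DataFrame
) -> pd.Series:
    """Per-sample flag: expression of >= 1 listed gene outside its interval.

    ``intervals`` is the reference-interval frame (columns xmin/xmax) from
    :func:`riskpath.deg_exceedance.reference_intervals`.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("gene set is empty")
    for g in genes:
        if g not in expr.values.index:
            raise KeyError(f"gene {g!r} not in expression matrix")
        if g not in intervals.index:
            raise KeyError(f"gene {g!r} has no reference interval")
    sub = expr.values.loc[genes]
    xmin = intervals.loc[genes, "xmin"].to_numpy()[:, None]
    xmax = intervals.loc[genes, "xmax"].to_numpy()[:, None]
    outside = (sub.to_numpy() > xmax) | (sub.to_numpy() < xmin)
    return pd.Series(outside.any(axis=0), index=expr.sample_ids, name="altered")


@dataclass
class KmResult:
    """Two-group Kaplan–Meier comparison."""

    curves: dict[str, pd.DataFrame]  # group -> (time, survival) step function
    statistic: float
    p_value: float
    group_sizes: dict[str, int]

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_sizes": self.group_sizes,
        }


def km_logrank(table: pd.DataFrame) -> KmResult:
    """Product-limit curves and log-rank test for altered vs unaltered.

    ``table`` needs columns ``time`` (>= 0), ``event`` (0/1) and ``altered``
    (bool).  Either group being empty is an error.
    """
    if (table["time"] < 0).any():
        raise ValueError("negative survival time")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")
    altered = table[table["altered"].astype(bool)]
    unaltered = table[~table["altered"].astype(bool)]
    if len(altered) == 0 or len(unaltered) == 0:
        raise ValueError("both altered and unaltered groups must be non-empty")
    curves = {}
    for name, grp in [("altered", altered), ("unaltered", unaltered)]:
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = logrank_test(
        altered["time"], unaltered["time"],
        event_observed_A=altered["event"], event_observed_B=unaltered["event"],
    )
    return KmResult(
        curves,
        float(res.test_statistic),
        float(res.p_value),
        {"altered": len(altered), "unaltered": len(unaltered)},
    )


def screen_genes(
    genes,
    expr: ExpressionMatrix,
    intervals: pd.DataFrame,
    surv: pd.DataFrame,
    alpha: float = 0.05,
) -> set[str]:
    """Keep genes whose single-gene altered-vs-unaltered log-rank p < alpha.

    ``surv`` has columns ``time`` and ``event`` indexed by sample id.  Genes
    with no altered (or no unaltered) sample cannot be tested and are dropped
    with a warning.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("gene set is empty")
    shared = [s for s in expr.sample_ids if s in surv.index]
    retained = set()
    for g in genes:
        flags = mark_altered(expr, [g], intervals).loc[shared]
        if flags.all() or not flags.any():
            logger.warning("gene %s: alteration flag is constant; untestable", g)
            continue
        table = surv.loc[shared, ["time", "event"]].copy()
        table["altered"] = flags
        if km_logrank(table).p_value < alpha:
            retained.add(g)
    if not retained:
        logger.warning("no gene passed the survival screen at alpha=%.3g", alpha)
    return retained


def integrate_gene_sets(tumor_genes, normal_genes) -> pd.Series:
    """Union of the two tissues' risk genes with provenance tags.

    Returns a Series gene -> {"tumor", "normal", "both"}.
    """
    tumor, normal = set(tumor_genes), set(normal_genes)
    tags = {}
    for g in sorted(tumor | normal):
        if g in tumor and g in normal:
            tags[g] = "both"
        elif g in tumor:
            tags[g] = "tumor"
        else:
            tags[g] = "normal"
    return pd.Series(tags, name="provenance", dtype=object)
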