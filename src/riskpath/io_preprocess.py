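"""Expression-matrix container, tabular I/O, and preprocessing steps.

The pipeline's substrate is a genes x samples matrix with a per-sample
annotation (prognosis group ``good``/``poor``, tissue ``tumor``/``normal``,
optionally survival time and event).  This module owns:

* reading/writing the tab-separated expression and annotation formats,
* per-gene z-score normalisation (population-SD convention, per tissue),
* the clustering prefilter (presence fraction + SD threshold),
* median centering (gene medians then sample medians, one pass each,
  Cluster-3.0 style).

Missing values are explicit ``NaN``; they are never silently treated as zero
expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = frozenset({"good", "poor"})
VALID_TISSUES = frozenset({"tumor", "normal"})

#: float format that round-trips IEEE doubles exactly through text
_ROUNDTRIP_FMT = "%.17g"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with sample annotation.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids.  Entries are
        floats; ``NaN`` marks a missing measurement.
    annotation
        DataFrame indexed by sample id with at least columns ``group``
        (``good``/``poor``) and ``tissue`` (``tumor``/``normal``); may carry
        ``time`` and ``event`` for survival analysis.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        gidx = self.values.index
        sidx = self.values.columns
        if gidx.duplicated().any():
            dup = gidx[gidx.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if sidx.duplicated().any():
            dup = sidx[sidx.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        missing = [s for s in sidx if s not in self.annotation.index]
        if missing:
            raise ValueError(f"sample {missing[0]!r} has no annotation")
        # align annotation to the matrix column order
        self.annotation = self.annotation.loc[list(sidx)].copy()
        bad_group = set(self.annotation["group"]) - VALID_GROUPS
        if bad_group:
            raise ValueError(f"invalid group label(s): {sorted(bad_group)}")
        bad_tissue = set(self.annotation["tissue"]) - VALID_TISSUES
        if bad_tissue:
            raise ValueError(f"invalid tissue label(s): {sorted(bad_tissue)}")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite (NaN marks missing)")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.annotation["group"]

    @property
    def tissues(self) -> pd.Series:
        return self.annotation["tissue"]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.annotation.index[self.annotation["group"] == group])

    def subset_tissue(self, tissue: str) -> "ExpressionMatrix":
        keep = self.annotation.index[self.annotation["tissue"] == tissue]
        return ExpressionMatrix(self.values[list(keep)], self.annotation.loc[list(keep)])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.annotation)

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.annotation)


# -- I/O -----------------------------------------------------------------------


def read_annotation(path) -> pd.DataFrame:
    """Read a sample annotation TSV (sample_id, group, tissue[, time, event])."""
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in ann.columns:
        raise ValueError(f"annotation file {path} lacks a 'sample_id' column")
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in annotation: {dup!r}")
    return ann.set_index("sample_id")


def read_expression(path, annotation_path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene_id, header = sample ids).

    Non-numeric cells and duplicated gene rows are hard errors naming the
    offending gene/sample; every sample column must appear in the annotation.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    try:
        values = raw.astype(float)
    except ValueError:
        for sample in raw.columns:
            converted = pd.to_numeric(raw[sample], errors="coerce")
            bad = converted.isna() & raw[sample].notna() & (raw[sample].str.lower() != "nan")
            if bad.any():
                gene = raw.index[bad][0]
                raise ValueError(
                    f"non-numeric cell at gene {gene!r}, sample {sample!r} in {path}"
                ) from None
        raise
    annotation = read_annotation(annotation_path)
    return ExpressionMatrix(values, annotation)


def write_expression(m: ExpressionMatrix, path, annotation_path=None) -> None:
    """Write the matrix (and optionally the annotation) as round-trip-exact TSV."""
    m.values.to_csv(path, sep="\t", index_label="gene_id", float_format=_ROUNDTRIP_FMT)
    if annotation_path is not None:
        m.annotation.to_csv(annotation_path, sep="\t", index_label="sample_id")


# -- normalisation -------------------------------------------------------------


def zscore_normalize(m: ExpressionMatrix, per_tissue: bool = True) -> ExpressionMatrix:
    """Z-score each gene (population SD) across samples, per tissue.

    Good and poor samples are pooled within a tissue; reference-interval
    statistics are recomputed on the good group afterwards, so pooling only
    fixes the scale.  A zero-variance gene is retained as an all-zero row with
    a logged warning — it can never exceed any reference interval.
    """
    out = m.values.copy()
    tissues = m.tissues.unique() if per_tissue else [None]
    for tissue in tissues:
        if tissue is None:
            cols = list(m.values.columns)
        else:
            cols = list(m.annotation.index[m.tissues == tissue])
        block = m.values[cols].to_numpy()
        mu = np.nanmean(block, axis=1, keepdims=True)
        sd = np.nanstd(block, axis=1, keepdims=True)  # population (ddof=0)
        flat = (sd == 0).ravel()
        if flat.any():
            names = [m.gene_ids[i] for i in np.flatnonzero(flat)[:5]]
            logger.warning(
                "%d zero-variance gene(s) set to all-zero rows (e.g. %s)",
                int(flat.sum()), ", ".join(names),
            )
        sd_safe = np.where(sd == 0, 1.0, sd)
        z = (block - mu) / sd_safe
        z[flat, :] = 0.0
        out[cols] = z
    return m.with_values(out)


def filter_for_clustering(
    m: ExpressionMatrix,
    presence_frac: float = 0.8,
    sd_min: float = 1.0,
) -> ExpressionMatrix:
    """Keep genes observed in >= ``presence_frac`` of samples with SD > ``sd_min``.

    "Observed" means non-missing (non-NaN).  With no missing values the filter
    reduces to the SD criterion.  SD uses the population convention over
    non-missing entries.  Gene order is preserved.
    """
    arr = m.values.to_numpy()
    present = ~np.isnan(arr)
    frac = present.mean(axis=1)
    sd = np.nanstd(arr, axis=1)
    keep = (frac >= presence_frac) & (sd > sd_min)
    if not keep.any():
        raise ValueError(
            "no gene passes the clustering prefilter; relax presence_frac/sd_min"
        )
    return m.with_values(m.values.loc[keep])


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract gene medians, then sample medians (one pass each, gene first)."""
    v = m.values.to_numpy(copy=True)
    v -= np.nanmedian(v, axis=1, keepdims=True)
    v -= np.nanmedian(v, axis=0, keepdims=True)
    return m.with_values(pd.DataFrame(v, index=m.values.index, columns=m.values.columns))
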