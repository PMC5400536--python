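"""Hierarchical clustering of samples on DEGs and at-risk subgroup calls.

Samples are clustered on the DEG rows of a filtered, median-centered matrix
with distance 1 - centered Pearson correlation and average linkage (the
Cluster-3.0 conventions).  Cutting the tree yields the prognosis clusters;
good-prognosis samples are then grouped by cluster into subgroups, and the
subgroup whose expression centroid lies nearest the poor-group centroid is
flagged as the at-risk subgroup — good-labelled patients whose profiles most
resemble the recurrent group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterTree:
    """Agglomerative merge history over samples."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    sample_ids: list[str]
    linkage_method: str
    similarity: str = "centered-pearson"

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)


def sample_distance_matrix(m: ExpressionMatrix, genes) -> pd.DataFrame:
    """Pairwise 1 - centered Pearson correlation between samples on given genes."""
    sub = m.subset_genes(genes)
    if sub.n_genes == 0:
        raise ValueError("none of the requested genes are in the matrix")
    profiles = sub.values.to_numpy().T  # samples x genes
    d = pdist(profiles, metric="correlation")
    if np.isnan(d).any():
        raise ValueError(
            "constant sample profile encountered; correlation distance undefined"
        )
    return pd.DataFrame(
        squareform(d), index=sub.sample_ids, columns=sub.sample_ids
    )


def cluster_samples(
    m: ExpressionMatrix, degs, linkage_method: str = "average"
) -> ClusterTree:
    """Average-linkage tree over samples using 1 - centered correlation on DEGs."""
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples to cluster")
    genes = [g for g in degs if g in m.values.index]
    if not genes:
        raise ValueError("no DEG present in the matrix")
    dist = sample_distance_matrix(m, genes)
    z = linkage(squareform(dist.to_numpy(), checks=False), method=linkage_method)
    return ClusterTree(z, list(dist.index), linkage_method)


def cut_to_clusters(tree: ClusterTree, k: int) -> pd.Series:
    """k-cluster partition from the tree; cluster ids are 1..k."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in [1, {tree.n_leaves}]")
    labels = fcluster(tree.linkage_matrix, t=k, criterion="maxclust")
    return pd.Series(labels, index=tree.sample_ids, name="cluster_id")


def cluster_purity(assignment: pd.Series, truth) -> pd.DataFrame:
    """Per-cluster majority label and its fraction, plus poor-group recall.

    Returns a DataFrame indexed by cluster id with columns ``majority``,
    ``purity`` and ``size``; the attribute ``poor_recall`` on the frame's
    ``attrs`` carries the fraction of poor samples captured by the poor
    group's modal cluster (the "14 of 15" statistic).
    """
    truth = pd.Series(dict(truth))
    rows = {}
    for cid, members in assignment.groupby(assignment):
        labels = truth.loc[members.index]
        counts = labels.value_counts()
        rows[cid] = {
            "majority": counts.index[0],
            "purity": counts.iloc[0] / len(labels),
            "size": len(labels),
        }
    frame = pd.DataFrame(rows).T.rename_axis("cluster_id")
    poor_samples = truth.index[truth == "poor"]
    if len(poor_samples):
        modal = assignment.loc[poor_samples].mode().iloc[0]
        frame.attrs["poor_recall"] = float(
            (assignment.loc[poor_samples] == modal).mean()
        )
        frame.attrs["poor_modal_cluster"] = modal
    return frame


def subgroup_assignment(
    assignment: pd.Series, truth, at_risk=()
) -> pd.DataFrame:
    """Flat table: sample_id, cluster_id, subgroup_id, at_risk.

    Subgroup ids number the good-prognosis subgroups (cluster partition
    restricted to good samples) in cluster-id order; poor samples get
    subgroup_id 0.
    """
    truth = pd.Series(dict(truth))
    good = truth.index[truth == "good"]
    good_clusters = sorted(assignment.loc[good].unique())
    sub_of_cluster = {c: i + 1 for i, c in enumerate(good_clusters)}
    rows = []
    at_risk = set(at_risk)
    for s in assignment.index:
        is_good = truth[s] == "good"
        rows.append(
            {
                "sample_id": s,
                "cluster_id": int(assignment[s]),
                "subgroup_id": sub_of_cluster[assignment[s]] if is_good else 0,
                "at_risk": s in at_risk,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def identify_at_risk(
    m: ExpressionMatrix, assignment: pd.Series, genes=None
) -> set[str]:
    """Good-prognosis subgroup nearest the poor-group centroid.

    Good samples are grouped by cluster id; each subgroup's centroid in the
    (DEG) expression space is compared to the poor-group centroid by
    Euclidean distance and the nearest subgroup is flagged.  With fewer than
    two good subgroups nothing is flagged (warned).  Ties go to the subgroup
    with the smaller cluster id (logged).
    """
    sub = m if genes is None else m.subset_genes(genes)
    truth = sub.groups
    good = truth.index[truth == "good"]
    poor = truth.index[truth == "poor"]
    if len(poor) == 0:
        logger.warning("no poor-prognosis samples; cannot flag an at-risk subgroup")
        return set()
    subgroups = {
        int(cid): list(members.index)
        for cid, members in assignment.loc[good].groupby(assignment.loc[good])
    }
    if len(subgroups) < 2:
        logger.warning(
            "good group forms a single subgroup; no at-risk subgroup flagged"
        )
        return set()
    poor_centroid = sub.values[list(poor)].mean(axis=1).to_numpy()
    best_cid, best_dist = None, np.inf
    for cid in sorted(subgroups):
        centroid = sub.values[subgroups[cid]].mean(axis=1).to_numpy()
        dist = float(np.linalg.norm(centroid - poor_centroid))
        if dist < best_dist - 1e-12:
            best_cid, best_dist = cid, dist
        elif abs(dist - best_dist) <= 1e-12:
            logger.info("at-risk tie between subgroups; keeping smaller id %s", best_cid)
    return set(subgroups[best_cid])
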