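"""Two-circle geometric classifier over (U, D) pathway deviation scores.

Each prognosis group gets a circle: its geometric center O (coordinate-wise
mean of the group's (U, D) points) and the minimal radius R whose circle
contains at least 80% of the group's own points (an order statistic of the
distances; the 80% coverage absorbs outliers).  A sample is then called by
circle membership:

* inside exactly one circle -> that circle's group,
* inside both              -> fuzzy (intersection),
* inside neither           -> fuzzy (isolation).

Fuzzy samples are withheld from classification; per-pathway precision is
computed over the confidently called samples only (precise1 = good-circle
precision, precise2 = poor-circle precision).  Pathways whose mean precision
exceeds a threshold (default 0.65) are ranked and the top few retained as
risk-associated.  Distances are Euclidean in the raw (U, D) plane; circle
boundaries are inclusive (distance <= R is inside).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CALL_GOOD = "good"
CALL_POOR = "poor"
CALL_FUZZY_INTERSECTION = "fuzzy_intersection"
CALL_FUZZY_ISOLATION = "fuzzy_isolation"


def geometric_center(points) -> np.ndarray:
    """Coordinate-wise arithmetic mean of (U, D) points."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("cannot take the geometric center of zero points")
    return pts.reshape(len(pts), -1).mean(axis=0)


def minimal_radius(points, center, coverage: float = 0.8) -> float:
    """Smallest R with >= ceil(coverage * n) points at distance <= R of center."""
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    dist = np.sort(np.linalg.norm(pts - np.asarray(center, dtype=float), axis=1))
    need = math.ceil(coverage * len(pts))
    return float(dist[need - 1])


@dataclass(frozen=True)
class CenterModel:
    """Fitted two-circle model for one pathway."""

    pathway_id: str
    center_good: tuple[float, float]
    center_poor: tuple[float, float]
    radius_good: float
    radius_poor: float
    coverage: float = 0.8


def fit(points_good, points_poor, coverage: float = 0.8, pathway_id: str = "") -> CenterModel:
    """Fit group centers and minimal coverage radii from training points."""
    pg = np.asarray(points_good, dtype=float).reshape(-1, 2)
    pp = np.asarray(points_poor, dtype=float).reshape(-1, 2)
    if len(pg) < 2 or len(pp) < 2:
        raise ValueError("need >= 2 training points in each group")
    cg = geometric_center(pg)
    cp = geometric_center(pp)
    return CenterModel(
        pathway_id=pathway_id,
        center_good=(float(cg[0]), float(cg[1])),
        center_poor=(float(cp[0]), float(cp[1])),
        radius_good=minimal_radius(pg, cg, coverage),
        radius_poor=minimal_radius(pp, cp, coverage),
        coverage=coverage,
    )


def classify(model: CenterModel, points, sample_ids=None) -> pd.Series:
    """Call each point by circle membership (inclusive boundaries).

    Returns a Series of calls in {good, poor, fuzzy_intersection,
    fuzzy_isolation}, indexed by ``sample_ids`` when given.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    dg = np.linalg.norm(pts - np.asarray(model.center_good), axis=1)
    dp = np.linalg.norm(pts - np.asarray(model.center_poor), axis=1)
    in_good = dg <= model.radius_good
    in_poor = dp <= model.radius_poor
    calls = np.where(
        in_good & in_poor,
        CALL_FUZZY_INTERSECTION,
        np.where(
            ~in_good & ~in_poor,
            CALL_FUZZY_ISOLATION,
            np.where(in_good, CALL_GOOD, CALL_POOR),
        ),
    )
    return pd.Series(calls, index=sample_ids, name="call")


@dataclass(frozen=True)
class PathwayEvaluation:
    pathway_id: str
    precise1: float  # good-circle precision
    precise2: float  # poor-circle precision
    fuzzy_count: int

    @property
    def mean_precision(self) -> float:
        return (self.precise1 + self.precise2) / 2.0


def evaluate_pathway(calls: pd.Series, truth, pathway_id: str = "") -> PathwayEvaluation:
    """Precision of the two circles against the true group labels.

    ``truth`` maps sample id -> {good, poor}.  Fuzzy samples are excluded
    from both denominators; an empty denominator yields precision 0 with a
    warning.
    """
    truth = pd.Series(dict(truth))
    missing = [s for s in calls.index if s not in truth.index]
    if missing:
        raise ValueError(f"no truth label for sample {missing[0]!r}")

    def _precision(label: str) -> float:
        called = calls.index[calls == label]
        if len(called) == 0:
            logger.warning(
                "pathway %s: no sample called %s; precision reported as 0",
                pathway_id, label,
            )
            return 0.0
        return float((truth.loc[called] == label).mean())

    fuzzy = int(calls.isin([CALL_FUZZY_INTERSECTION, CALL_FUZZY_ISOLATION]).sum())
    return PathwayEvaluation(pathway_id, _precision(CALL_GOOD), _precision(CALL_POOR), fuzzy)


def rank_pathways(
    evals, threshold: float = 0.65, top_k: int = 4
) -> list[PathwayEvaluation]:
    """Pathways with mean precision > threshold, best first, truncated to top_k.

    Ties are broken by higher min(precise1, precise2), then fewer fuzzy
    samples, then lexicographic pathway id.
    """
    passing = [e for e in evals if e.mean_precision > threshold]
    if not passing:
        logger.warning("no pathway exceeds mean precision %.2f", threshold)
        return []
    passing.sort(
        key=lambda e: (
            -e.mean_precision,
            -min(e.precise1, e.precise2),
            e.fuzzy_count,
            e.pathway_id,
        )
    )
    return passing[:top_k]


def risk_overlap(fuzzy_intersection_samples, at_risk_subgroup) -> float:
    """|fuzzy-intersection ∩ at-risk| / |fuzzy-intersection| (0 if empty)."""
    inter = set(fuzzy_intersection_samples)
    if not inter:
        logger.warning("no fuzzy-intersection samples; overlap reported as 0")
        return 0.0
    return len(inter & set(at_risk_subgroup)) / len(inter)


def evaluate_score_matrix(scores, annotation: pd.Series, coverage: float = 0.8):
    """Fit, classify and evaluate every pathway of a ScoreMatrix.

    ``annotation`` maps sample id -> group.  Training and evaluation use the
    same cohort.  Returns (models, calls, evaluations): dicts keyed by
    pathway id and a list of PathwayEvaluation.
    """
    truth = pd.Series(dict(annotation))
    good_ids = [s for s in scores.sample_ids if truth[s] == "good"]
    poor_ids = [s for s in scores.sample_ids if truth[s] == "poor"]
    models, calls, evals = {}, {}, []
    for pid in scores.pathway_ids:
        pts = pd.DataFrame(scores.points(pid), index=scores.sample_ids)
        model = fit(pts.loc[good_ids], pts.loc[poor_ids], coverage, pathway_id=pid)
        call = classify(model, pts.to_numpy(), sample_ids=pts.index)
        models[pid] = model
        calls[pid] = call
        evals.append(evaluate_pathway(call, truth, pathway_id=pid))
    return models, calls, evals


def evaluations_frame(evals, risk_ids=None) -> pd.DataFrame:
    """Summary table: pathway_id, precise1, precise2, fuzzy, mean_precision[, risk_flag]."""
    rows = [
        {
            "pathway_id": e.pathway_id,
            "precise1": e.precise1,
            "precise2": e.precise2,
            "fuzzy": e.fuzzy_count,
            "mean_precision": e.mean_precision,
        }
        for e in evals
    ]
    frame = pd.DataFrame(rows).set_index("pathway_id")
    if risk_ids is not None:
        frame["risk_flag"] = frame.index.isin(set(risk_ids))
    return frame
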