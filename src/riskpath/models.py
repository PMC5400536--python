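"""Cross-validated classifiers on risk-pathway features and hallmark enrichment.

The retained risk pathways' (U, D) columns form the feature table for a
random-forest (or RBF-SVM) classifier of prognosis group, evaluated by
stratified five-fold cross validation with per-fold ROC curves, a vertically
averaged mean curve on a fixed 101-point FPR grid, and mean AUC/accuracy.
Risk genes can additionally be tested for enrichment in user-supplied cancer
hallmark gene sets with a hypergeometric upper-tail test (p < 0.05, no
multiplicity correction by default, BH optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .deg_exceedance import fdr_correct
from .pathway_deviation import GeneSetCollection, ScoreMatrix

POSITIVE_LABEL = "poor"
FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class FeatureTable:
    """Samples x features matrix with prognosis labels."""

    x: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        if not self.x.index.equals(self.labels.index):
            self.labels = self.labels.loc[self.x.index]
        if self.x.isna().any().any():
            raise ValueError("feature table contains missing values")

    def to_frame(self) -> pd.DataFrame:
        out = self.x.copy()
        out["label"] = self.labels
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        return cls(frame.drop(columns="label"), frame["label"])


def build_features(scores: ScoreMatrix, risk_pathways, labels) -> FeatureTable:
    """(pathway, U) and (pathway, D) columns for each risk pathway, rank order."""
    risk_pathways = list(risk_pathways)
    if not risk_pathways:
        raise ValueError("risk pathway list is empty")
    unknown = [p for p in risk_pathways if p not in scores.pathway_ids]
    if unknown:
        raise KeyError(f"unknown pathway id {unknown[0]!r}")
    cols = {}
    for pid in risk_pathways:
        cols[f"{pid}|U"] = scores.u[pid]
        cols[f"{pid}|D"] = scores.d[pid]
    x = pd.DataFrame(cols, index=scores.u.index)
    return FeatureTable(x, pd.Series(dict(labels)).loc[x.index])


@dataclass
class FoldResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    accuracy: float


@dataclass
class CvResult:
    folds: list[FoldResult]
    mean_fpr: np.ndarray
    mean_tpr: np.ndarray
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))


def _make_model(model: str, seed: int):
    if model == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if model == "svm":
        return SVC(kernel="rbf", random_state=seed)
    raise ValueError(f"unknown model {model!r}; use 'random_forest' or 'svm'")


def cross_validate(
    features: FeatureTable,
    model: str = "random_forest",
    folds: int = 5,
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold CV with held-out ROC per fold and a mean curve.

    Decision scores are class-1 probabilities for the forest and the margin
    for the SVM; AUC is invariant to the choice as both are monotone in the
    underlying ranking.
    """
    y = (features.labels == POSITIVE_LABEL).astype(int).to_numpy()
    x = features.x.to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; use at most "
            f"{counts.min()} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_results = []
    tprs = []
    for train, test in skf.split(x, y):
        clf = _make_model(model, seed)
        clf.fit(x[train], y[train])
        if hasattr(clf, "predict_proba"):
            score = clf.predict_proba(x[test])[:, 1]
        else:
            score = clf.decision_function(x[test])
        fpr, tpr, _ = roc_curve(y[test], score)
        auc = roc_auc_score(y[test], score)
        acc = float((clf.predict(x[test]) == y[test]).mean())
        fold_results.append(FoldResult(fpr, tpr, float(auc), acc))
        interp = np.interp(FPR_GRID, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    return CvResult(fold_results, FPR_GRID.copy(), mean_tpr, seed)


@dataclass(frozen=True)
class EnrichmentResult:
    hallmark_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    significant: bool
    q_value: float | None = None


def hallmark_enrichment(
    query_genes,
    hallmark_sets: GeneSetCollection,
    universe,
    alpha: float = 0.05,
    bh: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of a gene set per hallmark.

    ``query_genes`` must be a subset of ``universe``; hallmark members are
    intersected with the universe first.  Significance is ``p < alpha`` on
    raw p-values (set ``bh=True`` to call on BH q-values instead).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query gene {sorted(stray)[0]!r} not in universe")
    n_univ, n_query = len(universe), len(query)
    raw = []
    for s in hallmark_sets:
        members = set(s.genes) & universe
        overlap = len(members & query)
        # P(X >= overlap), X ~ Hypergeom(N=n_univ, K=|members|, n=n_query)
        p = float(hypergeom.sf(overlap - 1, n_univ, len(members), n_query))
        raw.append((s.id, overlap, len(members), p))
    qvals = fdr_correct([r[3] for r in raw]) if bh else [None] * len(raw)
    out = []
    for (hid, overlap, size, p), q in zip(raw, qvals):
        crit = q if bh else p
        out.append(
            EnrichmentResult(
                hallmark_id=hid,
                overlap=overlap,
                set_size=size,
                query_size=n_query,
                universe_size=n_univ,
                p_value=p,
                significant=bool(crit < alpha),
                q_value=None if q is None else float(q),
            )
        )
    return out
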