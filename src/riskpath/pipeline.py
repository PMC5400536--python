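"""End-to-end per-tissue workflow with a deterministic run manifest.

Per tissue: z-normalize -> exceedance DEG calls -> hierarchical clustering
and at-risk subgroup -> pathway deviation scores -> two-circle classifier
and risk-pathway ranking -> random-forest CV on risk-pathway features ->
per-gene survival screen and KM comparison.  The two tissues are processed
independently and joined only at the final step, where the union of their
screened risk genes is tested against survival again.

The run is a pure function of (inputs, parameters, seed): every output file
is content-hashed into a JSON manifest, and repeated runs with the same
configuration produce byte-identical manifests (no timestamps in outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import center_classifier as cc
from . import clustering as cl
from . import deg_exceedance as deg
from . import io_preprocess as io
from . import models as md
from . import survival as sv
from .pathway_deviation import read_gmt, score_matrix

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Paths and parameters for a full two-tissue run."""

    expression: dict[str, str]   # tissue -> expression TSV
    annotation: dict[str, str]   # tissue -> annotation TSV
    gmt: str
    out_dir: str
    clinical: str | None = None
    hallmark_gmt: str | None = None
    alpha: float = 0.05
    n_perm: int = 10000
    seed: int = 0
    coverage: float = 0.8
    threshold: float = 0.65
    top_k: int = 4
    folds: int = 5
    k_clusters: dict[str, int] = field(default_factory=lambda: {"tumor": 3, "normal": 4})
    presence_frac: float = 0.8
    sd_min: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for tissue in self.expression:
            if tissue not in self.annotation:
                raise ValueError(f"no annotation path for tissue {tissue!r}")
        paths = [*self.expression.values(), *self.annotation.values(), self.gmt]
        if self.clinical is not None:
            paths.append(self.clinical)
        if self.hallmark_gmt is not None:
            paths.append(self.hallmark_gmt)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    summary: dict = {}
    clinical = (
        pd.read_csv(config.clinical, sep="\t", index_col="sample_id")
        if config.clinical
        else None
    )
    gene_sets = read_gmt(config.gmt)
    screened: dict[str, set[str]] = {}
    tissue_state: dict[str, dict] = {}

    for tissue in sorted(config.expression):
        stage = f"{tissue}:read"
        try:
            raw = io.read_expression(config.expression[tissue], config.annotation[tissue])
            z = io.zscore_normalize(raw)

            stage = f"{tissue}:deg"
            table = deg.deg_table(
                z, alpha=config.alpha, n_perm=config.n_perm, seed=config.seed
            )
            degs = table[table["q_value"] < config.alpha]
            outputs[f"{tissue}/degs"] = out / f"{tissue}_degs.tsv"
            _write_tsv(table, outputs[f"{tissue}/degs"])

            stage = f"{tissue}:cluster"
            filtered = io.filter_for_clustering(
                raw, presence_frac=config.presence_frac, sd_min=config.sd_min
            )
            centered = io.median_center(filtered)
            cluster_genes = [g for g in degs.index if g in centered.values.index]
            tree = cl.cluster_samples(centered, cluster_genes)
            k = config.k_clusters.get(tissue, 3)
            assignment = cl.cut_to_clusters(tree, k)
            purity = cl.cluster_purity(assignment, z.groups)
            at_risk = cl.identify_at_risk(centered, assignment, cluster_genes)
            sub = cl.subgroup_assignment(assignment, z.groups, at_risk)
            outputs[f"{tissue}/clusters"] = out / f"{tissue}_clusters.tsv"
            _write_tsv(sub, outputs[f"{tissue}/clusters"])
            summary[f"{tissue}_poor_recall"] = purity.attrs.get("poor_recall")

            stage = f"{tissue}:pathway_scores"
            scores = score_matrix(z, gene_sets, degs)
            outputs[f"{tissue}/scores"] = out / f"{tissue}_pathway_scores.tsv"
            _write_tsv(scores.to_long().set_index("sample_id"), outputs[f"{tissue}/scores"])

            stage = f"{tissue}:classify"
            _, calls, evals = cc.evaluate_score_matrix(scores, z.groups, config.coverage)
            ranked = cc.rank_pathways(evals, config.threshold, config.top_k)
            risk_ids = [e.pathway_id for e in ranked]
            eval_frame = cc.evaluations_frame(evals, risk_ids)
            outputs[f"{tissue}/pathway_eval"] = out / f"{tissue}_pathway_eval.tsv"
            _write_tsv(eval_frame, outputs[f"{tissue}/pathway_eval"])
            summary[f"{tissue}_risk_pathways"] = risk_ids
            overlap = {
                pid: cc.risk_overlap(
                    calls[pid].index[calls[pid] == cc.CALL_FUZZY_INTERSECTION], at_risk
                )
                for pid in risk_ids
            }
            summary[f"{tissue}_risk_overlap"] = overlap

            stage = f"{tissue}:model"
            if risk_ids:
                features = md.build_features(scores, risk_ids, z.groups)
                cv = md.cross_validate(
                    features, "random_forest", folds=config.folds, seed=config.seed
                )
                summary[f"{tissue}_rf_mean_auc"] = cv.mean_auc
                summary[f"{tissue}_rf_mean_accuracy"] = cv.mean_accuracy
                outputs[f"{tissue}/roc"] = out / f"{tissue}_rf_roc.json"
                outputs[f"{tissue}/roc"].write_text(
                    json.dumps(
                        {
                            "mean_fpr": cv.mean_fpr.tolist(),
                            "mean_tpr": cv.mean_tpr.tolist(),
                            "fold_auc": [f.auc for f in cv.folds],
                            "seed": cv.seed,
                        },
                        sort_keys=True,
                    )
                )

            stage = f"{tissue}:survival"
            risk_members = {
                g for pid in risk_ids for g in gene_sets[pid].genes
            }
            risk_genes = sorted(risk_members & set(degs.index))
            summary[f"{tissue}_n_risk_genes"] = len(risk_genes)
            tissue_state[tissue] = {
                "z": z,
                "intervals": deg.reference_intervals(z),
                "risk_genes": risk_genes,
            }
            if clinical is not None and risk_genes:
                kept = sv.screen_genes(
                    risk_genes, z, tissue_state[tissue]["intervals"], clinical,
                    alpha=config.alpha,
                )
                screened[tissue] = kept
                summary[f"{tissue}_n_screened_genes"] = len(kept)
                if kept:
                    shared = [s for s in z.sample_ids if s in clinical.index]
                    table_km = clinical.loc[shared, ["time", "event"]].copy()
                    table_km["altered"] = sv.mark_altered(
                        z, kept, tissue_state[tissue]["intervals"]
                    ).loc[shared]
                    km = sv.km_logrank(table_km)
                    summary[f"{tissue}_logrank_p"] = km.p_value
                    outputs[f"{tissue}/km"] = out / f"{tissue}_km.json"
                    outputs[f"{tissue}/km"].write_text(
                        json.dumps(km.summary(), sort_keys=True)
                    )
        except Exception as err:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # integration across tissues
    if len(screened) == 2 and all(screened.values()):
        tagged = sv.integrate_gene_sets(screened["tumor"], screened["normal"])
        outputs["integrated/genes"] = out / "integrated_risk_genes.tsv"
        tagged.rename_axis("gene_id").to_csv(outputs["integrated/genes"], sep="\t")
        flags = None
        for tissue, state in tissue_state.items():
            genes = [g for g in tagged.index if g in state["z"].values.index]
            f = sv.mark_altered(state["z"], genes, state["intervals"])
            flags = f if flags is None else (flags | f)
        shared = [s for s in flags.index if s in clinical.index]
        table_km = clinical.loc[shared, ["time", "event"]].copy()
        table_km["altered"] = flags.loc[shared]
        km = sv.km_logrank(table_km)
        summary["integrated_logrank_p"] = km.p_value
        outputs["integrated/km"] = out / "integrated_km.json"
        outputs["integrated/km"].write_text(json.dumps(km.summary(), sort_keys=True))

    manifest = {
        "parameters": {
            "alpha": config.alpha,
            "n_perm": config.n_perm,
            "seed": config.seed,
            "coverage": config.coverage,
            "threshold": config.threshold,
            "top_k": config.top_k,
            "folds": config.folds,
            "k_clusters": dict(sorted(config.k_clusters.items())),
        },
        "outputs": {
            name: {"path": str(path.relative_to(out)), "sha256": _sha256(path)}
            for name, path in sorted(outputs.items())
        },
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
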