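"""Seeded synthetic cohorts with the structure the pipeline assumes.

The generator emulates a paired tumor/normal recurrence cohort: 38
good-prognosis (non-recurrent) and 15 poor-prognosis (recurrent) patients
per tissue, i.i.d. standard-normal baseline expression, and four kinds of
planted structure:

* **risk genes** — concentrated in designated risk pathways; each gets a
  fixed-sign shift of ``shift_z`` z-units applied to an exact
  ``subgroup_frac`` fraction of poor samples (the heterogeneous
  subgroup-outlier pattern the exceedance test targets),
* **decoy genes** — a small ``decoy_shift_z`` mean shift in *all* poor
  samples that stays inside the reference interval (what a mean-difference
  test flags but the exceedance test should not),
* **diffuse dysregulation** — a few weak subgroup-outlier genes in every
  pathway, sharing one small per-pathway carrier subset (dysregulation hits
  gene modules in the same patients, not isolated genes in random patients),
  so non-risk pathways host a realistic trickle of borderline DEG members
  instead of being artificially empty,
* **at-risk good samples** — good-labelled patients carrying attenuated
  (50%) risk-gene shifts, so they cluster between the good core and the
  poor cloud; drawn per tissue (inherent, normal-tissue risk and acquired,
  tumor-tissue risk need not affect the same patients),
* **survival times** — exponential, with the hazard multiplied by
  ``hazard_ratio`` for patients carrying at least one risk-gene alteration,
  administratively censored to a target censoring fraction.

Tumor and normal tissue get disjoint risk-pathway sets, and each tissue's
risk-gene carriers are drawn from a tissue-specific *susceptible* subset of
the poor group (``tissue_carrier_frac``).  The two tissues therefore tag
partially distinct patient subsets — the complementarity premise of the
tumor+normal integration: either tissue alone misses some hazard-elevated
patients that the union recovers.  Everything derives from one integer
seed; the truth tables let every planted effect be verified by
recomputation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import ExpressionMatrix, write_expression
from .pathway_deviation import GeneSet, GeneSetCollection, write_gmt

TISSUES = ("tumor", "normal")


@dataclass
class SimulationConfig:
    """Cohort design parameters; defaults mirror the 38/15 paired design."""

    n_good: int = 38
    n_poor: int = 15
    n_genes: int = 2000
    n_pathways: int = 50
    genes_per_pathway: int = 38
    n_risk_pathways: int = 4
    n_risk_genes_per_pathway: int = 28
    n_decoy_genes: int = 100
    diffuse_genes_per_pathway: int = 4   # +/- 1 jitter; 0 disables
    diffuse_carriers_max: int = 4        # per-pathway carrier subset size 2..max
    subgroup_frac: float = 0.4   # fraction of poor samples carrying each shift
    tissue_carrier_frac: float = 0.8667  # fraction of poor samples susceptible per tissue
    shift_z: float = 4.0         # outlier shift, z units (0 => null cohort)
    decoy_shift_z: float = 0.5   # within-interval mean shift in all poor samples
    n_at_risk_good: int = 5
    at_risk_attenuation: float = 0.5
    hazard_ratio: float = 3.0
    censor_frac: float = 0.2
    baseline_median_months: float = 60.0
    heavy_tails: bool = False    # Student-t(5) baseline instead of Gaussian
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_good", "n_poor", "n_genes", "n_pathways", "genes_per_pathway",
            "n_risk_pathways", "n_risk_genes_per_pathway",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_pathways * self.genes_per_pathway + self.n_decoy_genes > self.n_genes:
            raise ValueError(
                "n_genes must cover pathway members plus pathway-free decoys"
            )
        if self.diffuse_genes_per_pathway < 0 or self.diffuse_carriers_max < 2:
            raise ValueError(
                "need diffuse_genes_per_pathway >= 0 and diffuse_carriers_max >= 2"
            )
        if self.diffuse_carriers_max > self.n_poor:
            raise ValueError("diffuse_carriers_max exceeds the poor group size")
        if 2 * self.n_risk_pathways > self.n_pathways:
            raise ValueError(
                "need n_pathways >= 2 * n_risk_pathways for disjoint tissue sets"
            )
        if self.n_risk_genes_per_pathway > self.genes_per_pathway:
            raise ValueError("n_risk_genes_per_pathway exceeds pathway size")
        if not 0 < self.subgroup_frac <= 1:
            raise ValueError("subgroup_frac must be in (0, 1]")
        if round(self.subgroup_frac * self.n_poor) < 1:
            raise ValueError("subgroup_frac * n_poor must round to >= 1 carrier")
        if not 0 < self.tissue_carrier_frac <= 1:
            raise ValueError("tissue_carrier_frac must be in (0, 1]")
        if round(self.subgroup_frac * self.n_poor) > round(
            self.tissue_carrier_frac * self.n_poor
        ):
            raise ValueError(
                "per-gene carriers cannot exceed the tissue's susceptible subset"
            )
        # shift_z = 0 is the null cohort; any planted shift must leave the
        # reference interval, and decoys must stay inside it
        if self.shift_z != 0 and self.shift_z <= 1.96:
            raise ValueError("shift_z must be 0 (null) or > 1.96 (outlier)")
        if not 0 <= self.decoy_shift_z < 1.96:
            raise ValueError("decoy_shift_z must be in [0, 1.96)")
        if self.n_at_risk_good < 0 or self.n_at_risk_good > self.n_good:
            raise ValueError("n_at_risk_good must be in [0, n_good]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must be in [0, 1)")


@dataclass
class SyntheticCohort:
    tumor: ExpressionMatrix
    normal: ExpressionMatrix
    pathways: GeneSetCollection
    survival: pd.DataFrame  # index sample_id; columns time, event
    truth: dict
    config: SimulationConfig

    def tissue(self, name: str) -> ExpressionMatrix:
        if name not in TISSUES:
            raise KeyError(name)
        return self.tumor if name == "tumor" else self.normal


def _balanced_subsets(pool, size: int, count: int, rng: np.random.Generator):
    """``count`` random subsets of ``pool`` of given ``size`` with balanced loads.

    Subsets are drawn by consuming random permutations of the pool block by
    block, so across the subsets every pool element is picked equally often
    (up to one).  Used for carrier assignment: each risk gene gets an exact
    carrier count while every susceptible sample ends up carrying a similar
    share of a pathway's genes — coherent pathway-level dysregulation rather
    than independent per-gene lottery.
    """
    pool = [int(x) for x in pool]
    if size > len(pool):
        raise ValueError("subset size exceeds pool size")
    order: list[int] = []
    for _ in range(count):
        if len(order) < size:
            fresh = [int(x) for x in rng.permutation(pool) if x not in order]
            order = order + fresh
        pick, order = order[:size], order[size:]
        yield sorted(pick)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(1, n + 1)]


def generate(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full two-tissue cohort with truth tables from one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_good + config.n_poor
    genes = _gene_ids(config.n_genes)
    samples = _sample_ids(n)
    groups = ["good"] * config.n_good + ["poor"] * config.n_poor
    good_idx = np.arange(config.n_good)
    poor_idx = np.arange(config.n_good, n)

    # pathway membership: a partition of the first n_pathways * gpp genes
    gpp = config.genes_per_pathway
    sets = []
    for p in range(config.n_pathways):
        members = genes[p * gpp : (p + 1) * gpp]
        sets.append(GeneSet(f"P{p + 1:03d}", f"synthetic pathway {p + 1}", tuple(members)))
    pathways = GeneSetCollection(sets)
    risk_pathway_ids = {
        "tumor": [s.id for s in sets[: config.n_risk_pathways]],
        "normal": [s.id for s in sets[config.n_risk_pathways : 2 * config.n_risk_pathways]],
    }

    n_carriers = int(round(config.subgroup_frac * config.n_poor))
    n_at_risk_carriers = (
        max(1, int(round(config.subgroup_frac * config.n_at_risk_good)))
        if config.n_at_risk_good
        else 0
    )

    # decoys are pathway-free; diffuse genes sit inside pathways but outside
    # every risk gene slot (either tissue)
    decoy_pool = genes[config.n_pathways * gpp :]
    risk_gene_slots = {
        g
        for pid in risk_pathway_ids["tumor"] + risk_pathway_ids["normal"]
        for g in pathways[pid].genes[: config.n_risk_genes_per_pathway]
    }

    matrices: dict[str, ExpressionMatrix] = {}
    truth: dict = {
        "risk_pathways": risk_pathway_ids,
        "at_risk_good_samples": {},
        "risk_genes": {},
        "decoy_genes": {},
        "diffuse_genes": {},
        "susceptible_poor": {},
        "altered_samples": {},
    }

    n_susceptible = int(round(config.tissue_carrier_frac * config.n_poor))
    elevated = np.zeros(n, dtype=bool)

    for tissue in TISSUES:
        if config.heavy_tails:
            base = rng.standard_t(df=5, size=(config.n_genes, n))
        else:
            base = rng.standard_normal((config.n_genes, n))

        susceptible = np.sort(rng.choice(poor_idx, size=n_susceptible, replace=False))
        truth["susceptible_poor"][tissue] = [samples[i] for i in susceptible]
        at_risk = sorted(
            int(i) for i in rng.choice(good_idx, size=config.n_at_risk_good, replace=False)
        )
        truth["at_risk_good_samples"][tissue] = [samples[i] for i in at_risk]
        if config.shift_z != 0:
            elevated[susceptible] = True
            elevated[at_risk] = True

        risk_genes: dict[str, dict] = {}
        for pid in risk_pathway_ids[tissue]:
            members = list(pathways[pid].genes)
            chosen = members[: config.n_risk_genes_per_pathway]
            carrier_sets = _balanced_subsets(susceptible, n_carriers, len(chosen), rng)
            ar_sets = (
                _balanced_subsets(at_risk, n_at_risk_carriers, len(chosen), rng)
                if n_at_risk_carriers
                else None
            )
            for j, g in enumerate(chosen):
                direction = "up" if j % 2 == 0 else "down"
                sign = 1.0 if direction == "up" else -1.0
                carriers = next(carrier_sets)
                gi = genes.index(g)
                base[gi, carriers] += sign * config.shift_z
                ar_carriers = next(ar_sets) if ar_sets is not None else []
                if ar_carriers:
                    base[gi, ar_carriers] += (
                        sign * config.at_risk_attenuation * config.shift_z
                    )
                risk_genes[g] = {
                    "pathway": pid,
                    "direction": direction,
                    "carriers": [samples[i] for i in carriers],
                    "at_risk_carriers": [samples[i] for i in ar_carriers],
                }

        decoys = sorted(rng.choice(decoy_pool, size=config.n_decoy_genes, replace=False))
        decoy_signs = rng.choice([-1.0, 1.0], size=len(decoys))
        for g, sign in zip(decoys, decoy_signs):
            base[genes.index(g), poor_idx] += sign * config.decoy_shift_z

        # module-coherent diffuse dysregulation: each pathway gets a few weak
        # outlier genes that share one small carrier subset of the poor group
        diffuse: dict[str, list[str]] = {}
        if config.diffuse_genes_per_pathway:
            lo = max(1, config.diffuse_genes_per_pathway - 1)
            hi = config.diffuse_genes_per_pathway + 2
            for s in sets:
                free = [g for g in s.genes if g not in risk_gene_slots]
                nd = min(len(free), int(rng.integers(lo, hi)))
                if nd == 0:
                    continue
                dgenes = rng.choice(free, size=nd, replace=False)
                k = int(rng.integers(2, config.diffuse_carriers_max + 1))
                subset = sorted(rng.choice(poor_idx, size=k, replace=False))
                for g in dgenes:
                    sign = float(rng.choice([-1.0, 1.0]))
                    base[genes.index(g), subset] += sign * config.shift_z
                    diffuse[str(g)] = [samples[i] for i in subset]

        annotation = pd.DataFrame(
            {"group": groups, "tissue": tissue}, index=pd.Index(samples, name="sample_id")
        )
        values = pd.DataFrame(base, index=pd.Index(genes, name="gene_id"), columns=samples)
        matrices[tissue] = ExpressionMatrix(values, annotation)
        truth["risk_genes"][tissue] = risk_genes
        truth["decoy_genes"][tissue] = [str(g) for g in decoys]
        truth["diffuse_genes"][tissue] = diffuse

    # hazard elevation: susceptible poor and at-risk goods of either tissue
    truth["altered_samples"] = [samples[i] for i in np.flatnonzero(elevated)]

    base_scale = config.baseline_median_months / np.log(2.0)
    scale = np.where(elevated, base_scale / config.hazard_ratio, base_scale)
    times = rng.exponential(scale=scale)
    event = np.ones(n, dtype=int)
    if config.censor_frac > 0:
        horizon = float(np.quantile(times, 1.0 - config.censor_frac))
        censored = times > horizon
        times = np.where(censored, horizon, times)
        event = np.where(censored, 0, 1)
    survival = pd.DataFrame(
        {"time": times, "event": event}, index=pd.Index(samples, name="sample_id")
    )

    return SyntheticCohort(
        tumor=matrices["tumor"],
        normal=matrices["normal"],
        pathways=pathways,
        survival=survival,
        truth=truth,
        config=config,
    )


def write_fixture(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write expression/annotation TSVs, GMT, clinical TSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for tissue in TISSUES:
        m = cohort.tissue(tissue)
        expr = out / f"expression_{tissue}.tsv"
        annot = out / f"annotation_{tissue}.tsv"
        write_expression(m, expr, annot)
        paths[f"expression_{tissue}"] = expr
        paths[f"annotation_{tissue}"] = annot
    paths["pathways"] = out / "pathways.gmt"
    write_gmt(cohort.pathways, paths["pathways"])
    paths["clinical"] = out / "clinical.tsv"
    cohort.survival.to_csv(paths["clinical"], sep="\t", float_format="%.17g")
    paths["truth"] = out / "truth.json"
    payload = {"config": asdict(cohort.config), "truth": cohort.truth}
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths
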