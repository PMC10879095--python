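"""End-to-end orchestration: score -> cluster -> candidates -> pairs -> evaluate.

``run_pipeline`` drives the full analysis from a :class:`RunConfig`, writing
per-stage outputs plus a JSON manifest recording versions, seeds and the
funnel counts at every stage.  Inputs are either file-backed cohorts or a
synthetic-cohort request; stage failures halt with the stage name while
earlier outputs are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__, candidates, io, scoring, subtype, synthetic
from .model import GenePairSignatureModel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration.

    Either ``synthetic`` (a dict of CohortSpec overrides; three cohorts are
    generated: discovery_gbm, discovery_glioma, validation) or ``cohorts``
    (name -> {'expression': path, 'survival': path, 'role': ...}) plus
    ``gene_sets`` (GMT path) must be provided.
    """

    out_dir: str = "rcdgp_run"
    synthetic: dict | None = None
    cohorts: dict | None = None
    gene_sets: str | None = None
    tau: float = 0.25
    cluster_reps: int = 200
    cluster_subsample: float = 0.8
    cluster_k: int = 2
    alpha: float = 0.05
    cgene_threshold: float = 0.3
    minprop: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if self.synthetic is None and self.cohorts is None:
            raise ValueError("config needs either 'synthetic' or 'cohorts'")
        if self.cohorts is not None:
            roles = [c.get("role") for c in self.cohorts.values()]
            for need in ("discovery_gbm", "discovery_glioma"):
                if need not in roles:
                    raise ValueError(f"config missing a cohort with role {need!r}")
            if self.gene_sets is None:
                raise ValueError("file-backed runs need 'gene_sets' (GMT path)")


def _load_cohorts(cfg: RunConfig):
    if cfg.synthetic is not None:
        spec = synthetic.CohortSpec(**{**cfg.synthetic, "seed": cfg.seed})
        expr_g, surv_g, truth = synthetic.generate_cohort(spec, sample_prefix="GL")
        spec_b = synthetic.CohortSpec(**{**cfg.synthetic,
                                         "seed": cfg.seed + 1})
        expr_b, surv_b, _ = synthetic.generate_cohort(spec_b, truth,
                                                      sample_prefix="GB")
        spec_v = synthetic.CohortSpec(**{**cfg.synthetic,
                                         "seed": cfg.seed + 2})
        expr_v, surv_v, _ = synthetic.generate_cohort(spec_v, truth,
                                                      sample_prefix="VA")
        sets = truth.gene_sets
        return ({"discovery_gbm": (expr_b, surv_b),
                 "discovery_glioma": (expr_g, surv_g),
                 "validation": (expr_v, surv_v)}, sets, truth)
    cohorts = {}
    for name, entry in cfg.cohorts.items():
        expr = io.read_expression(entry["expression"])
        surv = io.read_survival(entry["survival"])
        cohorts[entry.get("role", name)] = (expr, surv)
    sets = io.read_gmt(cfg.gene_sets)
    return cohorts, sets, None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: v for k, v in asdict(config).items()},
                      "stages": {}}
    stage = "load"
    try:
        cohorts, sets, truth = _load_cohorts(config)
        glioma = cohorts["discovery_glioma"]
        gbm = cohorts["discovery_gbm"]

        stage = "score"
        psm_glioma = scoring.ssgsea_scores(glioma[0], sets, tau=config.tau)
        psm_gbm = scoring.ssgsea_scores(gbm[0], sets, tau=config.tau)
        psm_glioma.to_tsv(out / "scores_discovery_glioma.tsv")
        manifest["stages"]["score"] = {"n_sets": len(sets),
                                       "n_samples": len(psm_glioma.samples)}

        stage = "cluster"
        cres = subtype.consensus_cluster(
            psm_glioma, k_range=(2, 3), reps=config.cluster_reps,
            subsample=config.cluster_subsample, seed=config.seed,
            chosen_k=config.cluster_k)
        assign = cres.assignment()
        assign.rename("cluster").to_csv(out / "cluster_assignments.tsv", sep="\t")
        lin = synthetic.linear_view(glioma[0])
        ga = lin.loc[:, assign[assign == 0].index]
        gb_ = lin.loc[:, assign[assign == 1].index]
        deg_tab = subtype.wilcoxon_deg(ga, gb_)
        deg_genes = subtype.cluster_deg_filter(deg_tab, p_max=config.alpha)
        deg_tab.to_csv(out / "cluster_deg.tsv", sep="\t")
        manifest["stages"]["cluster"] = {
            "chosen_k": cres.chosen_k, "pac": cres.pac,
            "cluster_sizes": assign.value_counts().to_dict(),
            "n_cluster_degs": len(deg_genes)}

        stage = "candidates"
        tabs = [candidates.per_rcd_association(gbm[0], psm_gbm, s,
                                               alpha=config.alpha)
                for s in psm_gbm.sets]
        cg = candidates.compute_cgenes(tabs, threshold=config.cgene_threshold)
        cg.drop(columns=["rho_values"]).to_csv(out / "cgenes.tsv", sep="\t")
        rcd_genes = candidates.rcd_related_genes(cg, deg_genes)
        pd.Series(rcd_genes).to_csv(out / "rcd_related_genes.tsv", sep="\t",
                                    index=False, header=["gene"])
        manifest["stages"]["candidates"] = {
            "n_cgenes": int(cg["is_cgene"].sum()),
            "n_rcd_related": len(rcd_genes)}

        stage = "pairs"
        model = GenePairSignatureModel(
            {"discovery_gbm": gbm, "discovery_glioma": glioma},
            genes=rcd_genes, alpha=config.alpha)
        results = model.fit()
        results.signature.to_tsv(out / "signature.tsv")
        manifest["stages"]["pairs"] = dict(results.funnel)

        stage = "evaluate"
        evals = {}
        for name, (expr, surv) in cohorts.items():
            rep = results.evaluate(expr, surv, cohort=name,
                                   minprop=config.minprop)
            score = results.predict(expr)
            score.to_csv(out / f"rcdgp_score_{name}.tsv", sep="\t",
                         index_label="sample")
            evals[name] = {k: v for k, v in rep.items() if k != "labels"}
        meta = results.meta_analysis()
        meta.to_frame().to_csv(out / "meta_forest.tsv", sep="\t")
        manifest["stages"]["evaluate"] = {
            "cohorts": evals,
            "meta": {"fixed_hr": meta.fixed_hr, "random_hr": meta.random_hr,
                     "Q": meta.Q, "I2": meta.I2}}
    except Exception:
        logger.error("pipeline halted at stage %r", stage)
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise

    files = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest["outputs"] = {p.name: _sha256(p) for p in files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
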