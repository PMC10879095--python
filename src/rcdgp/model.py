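"""Model/Results interface for the RCD gene-pair signature.

``GenePairSignatureModel`` holds the discovery data (two or more cohorts of
expression + survival restricted to the RCD-related gene list); ``fit()``
runs the pair construction, portability filter and dual-cohort univariate
Cox screen and returns a ``GenePairSignatureResults`` carrying the fitted
signature, per-pair estimates, funnel counts, and evaluation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pairs as gp
from . import survival_eval as se

__all__ = ["GenePairSignatureModel", "GenePairSignatureResults"]


class GenePairSignatureModel:
    """Dual-cohort gene-pair prognostic model.

    Parameters
    ----------
    discovery : mapping of cohort name -> (expression genes x samples,
        survival table).  The screen requires at least two cohorts; the
        first two are used as the dual screen.
    genes : candidate gene list (the RCD-related genes).
    presence : optional genes x datasets boolean frame for the portability
        filter over validation datasets.
    min_fraction : portability threshold (both genes present in at least
        this fraction of datasets).
    alpha : per-cohort screen significance level.
    """

    def __init__(self, discovery, genes, presence: pd.DataFrame | None = None,
                 min_fraction: float = 1.0, alpha: float = 0.05):
        self.discovery = dict(discovery)
        if len(self.discovery) < 2:
            raise ValueError("the dual screen needs two discovery cohorts")
        self.genes = sorted(dict.fromkeys(genes))
        self.presence = presence
        self.min_fraction = min_fraction
        self.alpha = alpha

    @classmethod
    def from_cohorts(cls, cohort_a, cohort_b, genes, names=("gbm", "glioma"),
                     **kw):
        return cls({names[0]: cohort_a, names[1]: cohort_b}, genes, **kw)

    def fit(self) -> "GenePairSignatureResults":
        names = list(self.discovery)
        a_name, b_name = names[0], names[1]
        expr_a, surv_a = self.discovery[a_name]
        expr_b, surv_b = self.discovery[b_name]
        shared = [g for g in self.genes
                  if g in expr_a.index and g in expr_b.index]
        pm_a = gp.build_pair_matrix(expr_a, shared)
        if self.presence is not None:
            pm_a = gp.filter_portable_pairs(pm_a, self.presence,
                                            self.min_fraction)
        else:
            pm_a = gp.filter_portable_pairs(
                pm_a, pd.DataFrame(True, index=shared, columns=["discovery"]),
                min_fraction=0.0, drop_constant=True)
        pm_b = gp.build_pair_matrix(expr_b, shared).subset(pm_a.pairs)
        screen_a = gp.univariate_cox_screen(pm_a, surv_a, cohort=a_name)
        screen_b = gp.univariate_cox_screen(pm_b, surv_b, cohort=b_name)
        signature = gp.select_signature(screen_a, screen_b, alpha=self.alpha)
        funnel = {
            "candidate_genes": len(self.genes),
            "genes_in_both_cohorts": len(shared),
            "pairs_built": int(len(shared) * (len(shared) - 1) // 2),
            "pairs_after_portability": pm_a.n_pairs,
            **{k: v for k, v in signature.provenance.items() if k != "screens"},
        }
        return GenePairSignatureResults(
            model=self, signature=signature,
            screens={a_name: screen_a, b_name: screen_b}, funnel=funnel)


@dataclass
class GenePairSignatureResults:
    """Fitted signature with prediction, evaluation and summary."""

    model: GenePairSignatureModel
    signature: gp.GenePairSignature
    screens: dict[str, pd.DataFrame]
    funnel: dict
    _evals: dict = field(default_factory=dict, repr=False)

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        """Integer RCD.GP score for each sample of an expression matrix."""
        return gp.rcdgp_score(expr, self.signature)

    def evaluate(self, expr: pd.DataFrame, survival: pd.DataFrame,
                 cohort: str = "cohort", horizons=(12.0, 36.0, 60.0),
                 minprop: float = 0.1) -> dict:
        """Full prognostic evaluation of the score on one cohort.

        Returns a dict with the maximally selected cutpoint, high-vs-low Cox
        HR with CI, log-rank chi2/p, Harrell C-index and IPCW AUC at the
        requested horizons.
        """
        score = self.predict(expr)
        cut = se.max_sel_cutpoint(score, survival, minprop=minprop)
        high = (cut.labels == "high").astype(float).rename("high_risk")
        cox = se.cox_model(high.to_frame(), survival, multivariate=True)
        perf = se.concordance_and_auc(score, survival, horizons=horizons)
        report = {
            "cohort": cohort,
            "cutpoint": cut.cutpoint,
            "cutpoint_statistic": cut.statistic,
            "logrank_chi2": cut.statistic ** 2,
            "logrank_p": cut.p_selected,
            "logrank_p_corrected": cut.p_corrected,
            "hazard_ratio": float(cox.loc["high_risk", "hazard_ratio"]),
            "hr_ci": (float(cox.loc["high_risk", "ci_lower"]),
                      float(cox.loc["high_risk", "ci_upper"])),
            "log_hr": float(cox.loc["high_risk", "log_hr"]),
            "log_hr_se": float(cox.loc["high_risk", "log_hr_se"]),
            "c_index": perf["c_index"],
            "auc": perf["auc"],
            "n": perf["n"],
            "n_events": perf["n_events"],
            "labels": cut.labels,
        }
        self._evals[cohort] = report
        return report

    def meta_analysis(self) -> se.MetaResult:
        """Pool the high-vs-low log HRs over every evaluated cohort."""
        if not self._evals:
            raise ValueError("evaluate() at least one cohort first")
        names = list(self._evals)
        return se.meta_hr([self._evals[c]["log_hr"] for c in names],
                          [self._evals[c]["log_hr_se"] for c in names],
                          cohorts=names)

    def summary(self) -> str:
        lines = ["RCD gene-pair signature", "=" * 54]
        lines.append(f"pairs in signature : {len(self.signature)}")
        lines.append(f"genes in signature : {len(self.signature.genes)}")
        for k, v in self.funnel.items():
            lines.append(f"  funnel {k:<24s}: {v}")
        for cohort, rep in self._evals.items():
            lines.append("-" * 54)
            lines.append(f"cohort {cohort}: n={rep['n']}, events={rep['n_events']}")
            lo, hi = rep["hr_ci"]
            lines.append(f"  high-vs-low HR {rep['hazard_ratio']:.2f} "
                         f"(95% CI {lo:.2f}-{hi:.2f}), "
                         f"log-rank p {rep['logrank_p']:.2e} "
                         f"(selection-corrected {rep['logrank_p_corrected']:.2e})")
            aucs = ", ".join(
                f"{int(h)}m {a:.3f}" if a is not None else f"{int(h)}m n/a"
                for h, a in rep["auc"].items())
            lines.append(f"  C-index {rep['c_index']:.3f}; AUC {aucs}")
        return "\n".join(lines)
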