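"""Binary gene-pair indicators, the dual-cohort Cox screen and the RCD.GP score.

The signature's building block is the within-sample comparison

    Score(x, y) = 1  if E_x > E_y   else 0   (ties score 0)

for an unordered gene pair (x, y) held in canonical lexicographic orientation
(x < y).  Because the indicator depends only on the ordering of two genes
inside the same sample, the resulting integer score

    RCD.GPscore = sum_i Score_i

is invariant to any per-sample monotone transform of expression — i.e. to
the normalization applied upstream.  Pairs enter the signature when their
univariate Cox Wald p-value is below alpha in *both* discovery cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cox import cox_newton_univariate

logger = logging.getLogger(__name__)

__all__ = ["GenePairMatrix", "GenePairSignature", "build_pair_matrix",
           "filter_portable_pairs", "univariate_cox_screen",
           "select_signature", "rcdgp_score"]


@dataclass
class GenePairMatrix:
    """Pairs x samples binary indicator matrix with canonical pair order."""

    values: pd.DataFrame                 # index: MultiIndex (gene_x, gene_y)
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.values.index)

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    def subset(self, pairs) -> "GenePairMatrix":
        idx = pd.MultiIndex.from_tuples(list(pairs), names=["gene_x", "gene_y"])
        return GenePairMatrix(self.values.loc[idx], self.dropped_genes)


def build_pair_matrix(expr: pd.DataFrame, genes) -> GenePairMatrix:
    """All C(n, 2) unordered pair indicators over ``genes`` present in expr.

    Pairs are keyed (gene_x, gene_y) with gene_x < gene_y lexicographically;
    the entry is 1 iff E(gene_x) > E(gene_y) in that sample (ties give 0).
    Requested genes absent from the matrix are dropped and recorded.
    """
    genes = sorted(dict.fromkeys(genes))
    present = [g for g in genes if g in expr.index]
    dropped = [g for g in genes if g not in expr.index]
    if dropped:
        logger.warning("%d gene(s) absent from expression matrix, dropped "
                       "before pairing", len(dropped))
    if len(present) < 2:
        raise ValueError("need at least 2 genes present to build pairs")
    X = expr.loc[present].to_numpy(dtype=float)
    ix, iy = np.triu_indices(len(present), k=1)
    V = (X[ix] > X[iy]).astype(np.int8)
    index = pd.MultiIndex.from_arrays(
        [np.asarray(present)[ix], np.asarray(present)[iy]],
        names=["gene_x", "gene_y"])
    return GenePairMatrix(pd.DataFrame(V, index=index, columns=expr.columns),
                          dropped_genes=dropped)


def filter_portable_pairs(pm: GenePairMatrix, gene_presence: pd.DataFrame,
                          min_fraction: float = 1.0,
                          drop_constant: bool = True) -> GenePairMatrix:
    """Keep pairs portable across datasets and informative in discovery.

    ``gene_presence`` is genes x datasets boolean.  A pair survives when both
    genes are present in at least ``min_fraction`` of the datasets
    (min_fraction = 0 disables portability filtering); constant-indicator
    pairs (frequency 0 or 1 across the discovery samples) are additionally
    dropped unless ``drop_constant`` is False.
    """
    keep = np.ones(pm.n_pairs, dtype=bool)
    if min_fraction > 0:
        frac = gene_presence.mean(axis=1)
        gx = pm.values.index.get_level_values(0)
        gy = pm.values.index.get_level_values(1)
        okx = frac.reindex(gx).fillna(0.0).to_numpy() >= min_fraction
        oky = frac.reindex(gy).fillna(0.0).to_numpy() >= min_fraction
        keep &= okx & oky
    if drop_constant:
        mean = pm.values.to_numpy().mean(axis=1)
        keep &= (mean > 0.0) & (mean < 1.0)
    logger.info("portability filter: %d -> %d pairs", pm.n_pairs, int(keep.sum()))
    return GenePairMatrix(pm.values.loc[keep], pm.dropped_genes)


def univariate_cox_screen(pm: GenePairMatrix, survival: pd.DataFrame,
                          cohort: str = "cohort") -> pd.DataFrame:
    """Univariate Cox (Efron ties, Wald test) per pair indicator.

    Non-convergent or monotone-likelihood fits are flagged and assigned
    p = 1.  Returns a DataFrame indexed like the pair matrix.
    """
    common = pm.values.columns.intersection(survival.index)
    if len(common) < len(pm.values.columns):
        logger.warning("screen %s: %d sample(s) lack survival; dropped",
                       cohort, len(pm.values.columns) - len(common))
    surv = survival.loc[common]
    n_events = int(surv["event"].sum())
    if n_events == 0:
        raise ValueError("no events in survival table; screen impossible")
    if n_events < 10:
        logger.warning("screen %s: only %d events", cohort, n_events)
    X = pm.values[common].to_numpy(dtype=float)
    res = cox_newton_univariate(X, surv["time_months"].to_numpy(),
                                surv["event"].to_numpy())
    return pd.DataFrame({
        "hazard_ratio": np.exp(res["log_hr"]),
        "log_hr": res["log_hr"],
        "log_hr_se": res["se"],
        "p_value": res["p"],
        "converged": res["converged"],
        "cohort": cohort,
    }, index=pm.values.index)


@dataclass
class GenePairSignature:
    """Ordered pair list plus provenance of the dual-cohort screen."""

    pairs: list[tuple[str, str]]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        return sorted({g for p in self.pairs for g in p})

    def to_tsv(self, path) -> None:
        rows = []
        screens = self.provenance.get("screens", {})
        for gx, gy in self.pairs:
            row = {"pair_id": f"{gx}|{gy}", "gene_x": gx, "gene_y": gy}
            for cname, tab in screens.items():
                row[f"hr_{cname}"] = tab.loc[(gx, gy), "hazard_ratio"]
                row[f"p_{cname}"] = tab.loc[(gx, gy), "p_value"]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        meta = {k: v for k, v in self.provenance.items() if k != "screens"}
        meta["n_pairs"] = len(self.pairs)
        meta["n_genes"] = len(self.genes)
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_tsv(cls, path) -> "GenePairSignature":
        tab = pd.read_csv(path, sep="\t")
        pairs = [tuple(r) for r in tab[["gene_x", "gene_y"]].to_numpy()]
        return cls(pairs=pairs, provenance={"source": str(path)})


def select_signature(screenA: pd.DataFrame, screenB: pd.DataFrame,
                     alpha: float = 0.05) -> GenePairSignature:
    """Pairs with Wald p < alpha in both cohorts, canonical order."""
    common = screenA.index.intersection(screenB.index)
    a = screenA.loc[common, "p_value"] < alpha
    b = screenB.loc[common, "p_value"] < alpha
    kept = common[(a & b).to_numpy()]
    funnel = {
        "pair_universe": int(len(common)),
        "pass_cohort_a": int(a.sum()),
        "pass_cohort_b": int(b.sum()),
        "pass_both": int(len(kept)),
        "alpha": alpha,
    }
    if len(kept) == 0:
        raise ValueError(f"no pair passed p < {alpha} in both cohorts; "
                         f"funnel counts: {funnel}")
    pairs = sorted(kept.tolist())
    prov = dict(funnel)
    prov["screens"] = {
        str(screenA["cohort"].iloc[0]): screenA.loc[pairs],
        str(screenB["cohort"].iloc[0]): screenB.loc[pairs],
    }
    return GenePairSignature(pairs=pairs, provenance=prov)


def rcdgp_score(data: GenePairMatrix | pd.DataFrame,
                signature: GenePairSignature) -> pd.Series:
    """Integer RCD.GP score per sample: the sum of signature pair indicators.

    ``data`` is either a pair matrix containing every signature pair or an
    expression matrix containing every signature gene.  Missing pairs/genes
    raise with their names — scores are never imputed.
    """
    if isinstance(data, GenePairMatrix):
        have = set(data.values.index)
        missing = [p for p in signature.pairs if p not in have]
        if missing:
            raise KeyError(f"pair matrix lacks signature pairs: {missing[:5]}"
                           f"{'...' if len(missing) > 5 else ''}")
        if not signature.pairs:
            return pd.Series(0, index=data.values.columns, name="rcdgp_score")
        sub = data.values.loc[pd.MultiIndex.from_tuples(signature.pairs)]
        return pd.Series(sub.to_numpy().sum(axis=0), index=data.values.columns,
                         name="rcdgp_score")
    expr = data
    missing = sorted({g for p in signature.pairs for g in p} - set(expr.index))
    if missing:
        raise KeyError(f"expression matrix lacks signature genes: {missing}")
    total = np.zeros(expr.shape[1], dtype=int)
    for gx, gy in signature.pairs:
        total += (expr.loc[gx].to_numpy() > expr.loc[gy].to_numpy()).astype(int)
    return pd.Series(total, index=expr.columns, name="rcdgp_score")
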