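"""The RCD-related gene funnel: Ga/Gb sets, C.genes, and the final gene list.

For each cell-death programme r with single-sample activity score s_r:

* Ga(r) — genes whose expression correlates with s_r (Spearman p < 0.05);
* Gb(r) — genes differentially expressed between the high/low halves of the
  cohort split at the median of s_r (rank-sum p < 0.05);
* G(r)  = Ga(r) ∩ Gb(r).

A gene's geometric mean of |rho| over the programmes where it belongs to
G(r) defines C.gene status (geometric mean > 0.3).  The final RCD-related
gene list is the intersection of the C.genes with the cluster DEGs.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import PathwayScoreMatrix, median_split
from .subtype import wilcoxon_deg

logger = logging.getLogger(__name__)

__all__ = ["spearman_vs_score", "per_rcd_association", "compute_cgenes",
           "rcd_related_genes"]


def _spearman_exact_p(rho: float, score_ranks: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman rho (n <= 9)."""
    n = len(score_ranks)
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1) / 6.0
    target = abs(rho)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        d2 = float(((base - score_ranks[list(perm)]) ** 2).sum())
        r = 1.0 - d2 / denom
        if abs(r) >= target - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_vs_score(expr: pd.DataFrame, score: pd.Series):
    """Spearman rho and two-sided p of every gene against one score vector.

    p via the t approximation; exact permutation enumeration for n <= 9.
    Constant genes get rho = nan (to be excluded by the caller).
    """
    common = expr.columns.intersection(score.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned samples for Spearman")
    X = expr[common].to_numpy(dtype=float)
    s = score[common].to_numpy(dtype=float)
    n = len(common)
    rx = stats.rankdata(X, axis=1)
    rs = stats.rankdata(s)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    rs_c = rs - rs.mean()
    denom = np.sqrt((rx_c ** 2).sum(axis=1) * (rs_c ** 2).sum())
    constant = (X == X[:, :1]).all(axis=1) | (denom <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx_c @ rs_c) / denom
    rho = np.where(constant, np.nan, np.clip(rho, -1.0, 1.0))
    if n <= 9:
        p = np.array([
            np.nan if not np.isfinite(r) else _spearman_exact_p(r, rs)
            for r in rho])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return pd.Series(rho, index=expr.index), pd.Series(p, index=expr.index)


def per_rcd_association(expr: pd.DataFrame, scores: PathwayScoreMatrix,
                        rcd_set: str, alpha: float = 0.05) -> pd.DataFrame:
    """Ga/Gb/G membership of every gene for one cell-death programme.

    ``expr`` may be on any monotone per-sample scale: both the Spearman test
    and the rank-sum test see only ranks.  Constant genes are excluded and
    logged.
    """
    if rcd_set not in scores.scores.index:
        raise KeyError(f"set {rcd_set!r} not scored")
    score = scores.scores.loc[rcd_set]
    if not expr.columns.equals(score.index):
        expr = expr[score.index]  # raises KeyError if samples are missing
    rho, p = spearman_vs_score(expr, score)
    excluded = rho.index[~np.isfinite(rho)]
    if len(excluded):
        logger.info("set %s: %d constant gene(s) excluded from association",
                    rcd_set, len(excluded))
    groups = median_split(scores, rcd_set)
    hi = expr.loc[:, groups[groups == "high"].index]
    lo = expr.loc[:, groups[groups == "low"].index]
    deg = wilcoxon_deg(hi, lo)
    tab = pd.DataFrame({
        "rcd_set": rcd_set,
        "spearman_rho": rho,
        "spearman_p": p,
        "wilcoxon_p": deg["p_value"].reindex(expr.index),
    })
    tab = tab.loc[np.isfinite(tab["spearman_rho"])]
    tab["in_ga"] = tab["spearman_p"] < alpha
    tab["in_gb"] = tab["wilcoxon_p"] < alpha
    tab["in_g"] = tab["in_ga"] & tab["in_gb"]
    tab.attrs["excluded_genes"] = list(excluded)
    return tab


def compute_cgenes(assoc_tables, threshold: float = 0.3) -> pd.DataFrame:
    """C.gene records from per-programme association tables.

    For each gene, |rho| values are collected over the programmes where the
    gene is in G(r); the geometric mean (prod |rho_i|)^(1/n) over those n
    programmes defines ``is_cgene`` (> threshold, strict).  The geometric
    mean is taken on |rho| because a geometric mean of signed correlations is
    undefined for negative factors; the sign profile is retained.
    """
    tables = list(assoc_tables)
    if not tables:
        raise ValueError("need at least one association table")
    longtab = pd.concat([t[t["in_g"]] for t in tables])
    records = []
    for gene, grp in longtab.groupby(level=0, sort=True):
        absr = grp["spearman_rho"].abs().to_numpy()
        n = len(absr)
        gm = 0.0 if np.any(absr == 0) else float(
            math.exp(np.log(absr).mean()))
        records.append({
            "gene": gene,
            "member_sets": sorted(grp["rcd_set"]),
            "n_sets": n,
            "rho_values": list(grp["spearman_rho"].round(6)),
            "geometric_mean": gm,
            "is_cgene": gm > threshold,
        })
    cols = ["gene", "member_sets", "n_sets", "rho_values",
            "geometric_mean", "is_cgene"]
    if not records:
        return pd.DataFrame(columns=cols).set_index("gene")
    return pd.DataFrame(records, columns=cols).set_index("gene")


def rcd_related_genes(cgenes: pd.DataFrame | list, cluster_deg_genes) -> list[str]:
    """Intersection of C.genes with cluster DEGs, sorted."""
    if isinstance(cgenes, pd.DataFrame):
        cset = set(cgenes.index[cgenes["is_cgene"]])
    else:
        cset = set(cgenes)
    dset = set(cluster_deg_genes)
    if not cset or not dset:
        raise ValueError("both the C.gene list and the DEG list must be nonempty")
    out = sorted(cset & dset)
    if not out:
        logger.warning("C.genes and cluster DEGs are disjoint; no RCD-related genes")
    return out
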