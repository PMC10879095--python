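"""Consensus clustering of RCD activity profiles and differential expression.

Consensus clustering follows the resampling recipe: repeatedly subsample the
samples, cluster each subsample with PAM (k-medoids), and record for every
sample pair how often they co-cluster among the draws in which both were
present.  Final assignments come from average-linkage hierarchical clustering
of 1 - consensus, and the proportion of ambiguous clustering (PAC) ranks the
candidate k.

Differential expression between groups uses the two-sided Wilcoxon rank-sum
test (exact enumeration for small groups, normal approximation with tie and
continuity correction otherwise) with Benjamini-Hochberg adjustment, and
log2 fold changes computed on a linear-scale view with a pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .scoring import PathwayScoreMatrix

logger = logging.getLogger(__name__)

__all__ = ["ConsensusResult", "consensus_cluster", "pam", "wilcoxon_deg",
           "cluster_deg_filter"]


def pam(D: np.ndarray, k: int, rng: np.random.Generator | None = None,
        max_swaps: int = 200) -> np.ndarray:
    """k-medoids (PAM) on a precomputed distance matrix: BUILD + SWAP.

    Deterministic given D and k (the greedy BUILD phase needs no randomness;
    rng is accepted for interface symmetry).  Returns integer labels 0..k-1.
    """
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError("k out of range")
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dmin = D[medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding each candidate: total reduction in nearest-medoid dist
        gain = np.maximum(dmin[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        c = int(np.argmax(gain))
        medoids.append(c)
        np.minimum(dmin, D[c], out=dmin)
    medoids = np.asarray(medoids)
    for _ in range(max_swaps):
        Dm = D[medoids]                      # (k, n)
        best_delta, best = 0.0, None
        cost = Dm.min(axis=0).sum()
        for mi in range(k):
            others = np.delete(medoids, mi)
            dmin_excl = D[others].min(axis=0) if len(others) else np.full(n, np.inf)
            cand_cost = np.minimum(dmin_excl[None, :], D).sum(axis=1)
            cand_cost[medoids] = np.inf
            h = int(np.argmin(cand_cost))
            delta = cand_cost[h] - cost
            if delta < best_delta - 1e-12:
                best_delta, best = delta, (mi, h)
        if best is None:
            break
        medoids[best[0]] = best[1]
    labels = np.argmin(D[medoids], axis=0)
    return labels


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, assignments and PAC, plus the chosen k."""

    consensus: dict[int, pd.DataFrame]
    assignments: dict[int, pd.Series]
    pac: dict[int, float]
    chosen_k: int
    rep_count: int
    subsample_fraction: float
    seed: int
    metric: str = "euclidean"
    extras: dict = field(default_factory=dict)

    def assignment(self, k: int | None = None) -> pd.Series:
        return self.assignments[self.chosen_k if k is None else k]


def consensus_cluster(profile: PathwayScoreMatrix | pd.DataFrame,
                      k_range=(2, 3, 4, 5), reps: int = 1000,
                      subsample: float = 0.8, seed: int = 0,
                      metric: str = "euclidean",
                      chosen_k: int | None = None) -> ConsensusResult:
    """Consensus PAM clustering of samples on their pathway-score profile.

    ``profile`` is sets x samples (samples are clustered).  ``metric`` is
    'euclidean' (default) or 'correlation'.  ``chosen_k`` overrides the
    PAC-argmin choice.  PAC(k) = CDF(0.9) - CDF(0.1) of the off-diagonal
    consensus values.
    """
    df = profile.scores if isinstance(profile, PathwayScoreMatrix) else profile
    X = df.to_numpy(dtype=float).T          # samples x features
    samples = list(df.columns)
    n = len(samples)
    k_range = sorted(set(int(k) for k in k_range))
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not (0.0 < subsample <= 1.0):
        raise ValueError("subsample must lie in (0, 1]")
    if k_range[0] < 2 or k_range[-1] > n // 3:
        raise ValueError(f"k_range must lie within [2, n/3] = [2, {n // 3}]")
    D = squareform(pdist(X, metric=metric))
    m = max(2, int(round(subsample * n)))
    rng = np.random.default_rng(seed)

    consensus, assignments, pac = {}, {}, {}
    for k in k_range:
        co = np.zeros((n, n))
        tot = np.zeros((n, n))
        for _ in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            sub = np.ix_(idx, idx)
            tot[sub] += 1.0
            labels = pam(D[sub], k)
            for c in range(k):
                mem = idx[labels == c]
                co[np.ix_(mem, mem)] += 1.0
        never = np.diag(tot) == 0
        if never.any():
            raise ValueError(
                f"{int(never.sum())} sample(s) never subsampled over {reps} "
                "repetitions; increase reps")
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(tot > 0, co / np.where(tot > 0, tot, 1.0), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        Z = average(squareform(1.0 - M, checks=False))
        lab = fcluster(Z, t=k, criterion="maxclust") - 1
        off = M[np.triu_indices(n, 1)]
        pac[k] = float(np.mean(off <= 0.9) - np.mean(off <= 0.1))
        consensus[k] = pd.DataFrame(M, index=samples, columns=samples)
        assignments[k] = pd.Series(lab, index=samples, name=f"k{k}")
    best_k = chosen_k if chosen_k is not None else min(pac, key=pac.get)
    if best_k not in consensus:
        raise ValueError(f"chosen_k={best_k} not in k_range")
    return ConsensusResult(consensus=consensus, assignments=assignments,
                           pac=pac, chosen_k=int(best_k), rep_count=reps,
                           subsample_fraction=subsample, seed=seed,
                           metric=metric)


def _ranksum_p(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (rows of A, B).

    Exact enumeration when both groups have <= 10 samples and the gene has no
    cross-group ties; otherwise the normal approximation with tie and
    continuity correction.
    """
    n1, n2 = A.shape[1], B.shape[1]
    p = mannwhitneyu(A, B, axis=1, alternative="two-sided",
                     method="asymptotic", use_continuity=True).pvalue
    p = np.asarray(p, dtype=float)
    if n1 <= 10 and n2 <= 10:
        for i in range(A.shape[0]):
            pooled = np.concatenate([A[i], B[i]])
            if np.unique(pooled).size == pooled.size:  # no ties -> exact valid
                p[i] = mannwhitneyu(A[i], B[i], alternative="two-sided",
                                    method="exact").pvalue
    # degenerate genes (identical constant in both groups) give nan -> p = 1
    constant = np.all(np.concatenate([A, B], axis=1)
                      == np.concatenate([A, B], axis=1)[:, :1], axis=1)
    p[constant | ~np.isfinite(p)] = 1.0
    return np.minimum(p, 1.0)


def wilcoxon_deg(exprA: pd.DataFrame, exprB: pd.DataFrame,
                 pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene rank-sum DEG table between two sample groups.

    Inputs are linear-scale (TPM-like) genes x samples matrices sharing a
    gene index.  Returns gene, group means, log2FC (with pseudocount),
    p_value and BH-adjusted p.
    """
    if exprA.shape[1] < 2 or exprB.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    common = exprA.index.intersection(exprB.index)
    if len(common) == 0:
        raise ValueError("no common genes between groups")
    A = exprA.loc[common].to_numpy(dtype=float)
    B = exprB.loc[common].to_numpy(dtype=float)
    p = _ranksum_p(A, B)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": common, "mean_a": mean_a, "mean_b": mean_b,
        "log2fc": lfc, "p_value": p, "adjusted_p": adj,
    }).set_index("gene")


def cluster_deg_filter(table: pd.DataFrame, p_max: float = 0.05,
                       lfc_min: float = 1.0) -> list[str]:
    """Genes with p < p_max and |log2FC| > lfc_min (both strict)."""
    keep = (table["p_value"] < p_max) & (table["log2fc"].abs() > lfc_min)
    return sorted(table.index[keep])
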