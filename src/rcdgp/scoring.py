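"""Single-sample gene-set activity scoring.

Two rank-based scorers:

* ``ssgsea_scores`` — per-sample weighted running-sum enrichment for bulk
  cohorts.  For a sample with N genes ranked by decreasing expression, the
  enrichment score of set S is

      ES(S) = sum_{i=1..N} [ P_in^w(i) - P_out(i) ]

  where P_in^w is the cumulative fraction of rank-weight r^tau over in-set
  genes (r the ascending expression rank, highest-expressed gene r = N, ties
  averaged) and P_out the uniform cumulative fraction over out-of-set genes.

* ``aucell_scores`` — per-cell area under the gene-set recovery curve over
  the top-ranked fraction of genes, normalised to [0, 1] by the maximal
  attainable area.

Both depend on expression only through within-sample ranks, so they are
invariant to any strictly increasing per-sample transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayScoreMatrix",
    "ssgsea_scores",
    "aucell_scores",
    "median_split",
    "dominant_rcd",
    "DegenerateSplitError",
]


class DegenerateSplitError(ValueError):
    """Raised when a median split is impossible because the score is constant."""


@dataclass
class PathwayScoreMatrix:
    """Sets x samples score matrix with provenance tags."""

    scores: pd.DataFrame
    method: str                      # "ssgsea" | "aucell"
    params: dict = field(default_factory=dict)
    normalization: str = "none"
    seed: int | None = None

    @property
    def sets(self) -> list[str]:
        return list(self.scores.index)

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path, sidecar: bool = True) -> None:
        self.scores.to_csv(path, sep="\t")
        if sidecar:
            import json
            meta = {"method": self.method, "params": self.params,
                    "normalization": self.normalization, "seed": self.seed}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)


def _intersect_sets(sets, universe, *, allow_full: bool = False):
    """Restrict gene sets to the expression universe; drop absent genes."""
    out = {}
    uni = set(universe)
    for name, members in sets.items():
        kept = [g for g in dict.fromkeys(members) if g in uni]
        dropped = len(set(members)) - len(kept)
        if dropped:
            logger.info("set %s: %d gene(s) absent from matrix, dropped", name, dropped)
        if not kept:
            raise ValueError(f"gene set {name!r} has no genes in the expression matrix")
        if not allow_full and len(kept) == len(uni):
            raise ValueError(f"gene set {name!r} covers the whole gene universe")
        out[name] = kept
    return out


def ssgsea_scores(expr: pd.DataFrame, sets, tau: float = 0.25,
                  normalize: bool = True) -> PathwayScoreMatrix:
    """ssGSEA enrichment scores for every set in every sample.

    Parameters
    ----------
    expr : genes x samples expression matrix (any monotone scale).
    sets : mapping of set name -> gene identifiers.
    tau : rank-weight exponent (0 gives unweighted cumulative fractions).
    normalize : divide all entries by (max - min) over the whole matrix.
    """
    sets = _intersect_sets(sets, expr.index)
    X = expr.to_numpy(dtype=float)
    n_genes, n_samp = X.shape
    # ascending ranks, ties averaged: highest-expressed gene has rank N
    ranks = rankdata(X, axis=0)
    # deterministic decreasing-expression ordering per sample
    order = np.argsort(-X, axis=0, kind="stable")
    ranks_ord = np.take_along_axis(ranks, order, axis=0)
    weights = ranks_ord ** tau

    gene_pos = {g: i for i, g in enumerate(expr.index)}
    out = np.empty((len(sets), n_samp))
    for si, (name, members) in enumerate(sets.items()):
        mask = np.zeros(n_genes, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        in_ord = mask[order]
        w_in = np.where(in_ord, weights, 0.0)
        p_in = np.cumsum(w_in, axis=0) / w_in.sum(axis=0, keepdims=True)
        out_ord = ~in_ord
        p_out = np.cumsum(out_ord, axis=0) / (n_genes - len(members))
        out[si] = (p_in - p_out).sum(axis=0)

    tag = "none"
    if normalize:
        span = out.max() - out.min()
        if span > 0:
            out = out / span
        tag = "matrix_max_minus_min"
    scores = pd.DataFrame(out, index=list(sets), columns=expr.columns)
    return PathwayScoreMatrix(scores, method="ssgsea", params={"tau": tau},
                              normalization=tag)


def aucell_scores(expr: pd.DataFrame, sets, top_frac: float = 0.05,
                  seed: int = 0) -> PathwayScoreMatrix:
    """AUCell recovery-curve scores in [0, 1] per set per cell.

    Genes are ranked by decreasing expression within each cell, ties broken by
    a seeded random permutation (the same permutation for every cell, recorded
    via ``seed``).  With K = ceil(top_frac * n_genes) the score is

        sum_{k=1..K} H(k)  /  sum_{k=1..K} min(k, m),   m = min(|S|, K)

    where H(k) counts in-set genes among the top k.
    """
    if not (0.0 < top_frac < 1.0):
        raise ValueError("top_frac must lie strictly between 0 and 1")
    sets = _intersect_sets(sets, expr.index, allow_full=True)
    X = expr.to_numpy(dtype=float)
    n_genes, n_cells = X.shape
    K = math.ceil(top_frac * n_genes)
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(n_genes)
    # lexsort: primary key -expression, secondary the random permutation
    order = np.lexsort((np.broadcast_to(tiebreak[:, None], X.shape), -X), axis=0)
    top = order[:K]                     # (K, cells) gene indices

    gene_pos = {g: i for i, g in enumerate(expr.index)}
    rank_weight = (K - np.arange(K))[:, None].astype(float)  # position p gets K-p+1
    out = np.empty((len(sets), n_cells))
    for si, (name, members) in enumerate(sets.items()):
        mask = np.zeros(n_genes, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        in_top = mask[top]
        area = (in_top * rank_weight).sum(axis=0)
        m = min(len(members), K)
        max_area = m * (m + 1) / 2 + (K - m) * m
        out[si] = area / max_area
    scores = pd.DataFrame(out, index=list(sets), columns=expr.columns)
    return PathwayScoreMatrix(scores, method="aucell",
                              params={"top_frac": top_frac, "K": K}, seed=seed)


def median_split(scores: PathwayScoreMatrix, set_name: str) -> pd.Series:
    """Label samples 'high' (score > median) or 'low' for one set."""
    if set_name not in scores.scores.index:
        raise KeyError(f"set {set_name!r} not in score matrix")
    row = scores.scores.loc[set_name]
    if len(row) < 2:
        raise ValueError("median split needs at least 2 samples")
    med = row.median()
    if row.nunique() == 1:
        raise DegenerateSplitError(
            f"score of set {set_name!r} is constant; split undefined")
    return pd.Series(np.where(row > med, "high", "low"), index=row.index,
                     name=set_name)


def dominant_rcd(scores: PathwayScoreMatrix) -> pd.DataFrame:
    """Per-cell dominant programme: the set with the highest score.

    Ties are broken by lexicographically first set name and flagged in the
    ``tie`` column.
    """
    df = scores.scores.sort_index()  # lexicographic order => idxmax breaks ties
    if df.empty:
        raise ValueError("score matrix has no sets")
    arr = df.to_numpy()
    best = arr.argmax(axis=0)
    mx = arr.max(axis=0)
    tie = (arr == mx).sum(axis=0) > 1
    return pd.DataFrame(
        {"dominant": df.index.to_numpy()[best], "tie": tie}, index=df.columns)
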