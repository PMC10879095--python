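"""Synthetic multi-cohort glioma-like data with planted ground truth.

The generator emulates the study design the package targets: two (or more)
bulk expression cohorts sharing a gene universe, latent regulated-cell-death
(RCD) pathway activities that drive gene-set scores, two planted tumour
subtypes separated in pathway-activity space, overall survival tied to a
planted gene-pair score, and a small single-cell count matrix in which each
cell type over-expresses one designated gene set.

Expression is produced on the log2(TPM+1) scale as

    x_gs = mu_g + sum_k L_gk a_ks + eps_gs

with a factor-loading matrix L (genes x sets), latent activities a
(sets x samples) and Gaussian residual noise.  Survival times are Weibull
(shape 1.2) under proportional hazards with linear predictor

    pair_beta * z(planted pair score) + cluster_beta * 1[subtype B]

and independent exponential censoring whose rate is solved numerically so the
realised censoring fraction matches ``censor_rate`` in expectation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

#: canonical names for the 18 regulated-cell-death programmes used as
#: synthetic gene-set labels (alphabetical so set order is deterministic)
RCD_SET_NAMES = [
    "alkaliptosis", "anoikis", "apoptosis", "autophagy", "autosis",
    "cuproptosis", "disulfidptosis", "entotic_cell_death", "ferroptosis",
    "immunogenic_cell_death", "lysosome_dependent_cell_death", "methuosis",
    "necroptosis", "netotic_cell_death", "oxeiptosis", "paraptosis",
    "parthanatos", "pyroptosis",
]


def _set_names(n_sets: int) -> list[str]:
    names = list(RCD_SET_NAMES)
    while len(names) < n_sets:
        names.append(f"rcd_extra_{len(names) + 1:02d}")
    return names[:n_sets]


@dataclass
class CohortSpec:
    """Parameters of one synthetic bulk cohort.

    Defaults approximate the bulk glioma cohorts the method was designed for:
    a few hundred patients, 18 pathway programmes of ~40 genes inside a
    1000-gene universe, a 2-SD subtype separation in pathway activity, a
    planted gene-pair effect of log-HR 1 per SD of the pair score, a median
    baseline survival of about two years and ~30% censoring.
    """

    n_samples: int = 300
    n_genes: int = 1000
    n_sets: int = 18
    set_size: int = 40
    cluster_shift: float = 2.0          # SD shift of pathway activity, subtype B vs A
    pair_beta: float = 1.0              # log HR per SD of the planted pair score
    baseline_hazard_scale: float = 24.0  # baseline median survival, months
    censor_rate: float = 0.3
    noise_sd: float = 1.0               # residual SD, log2 scale
    seed: int = 0
    # secondary knobs (not part of the headline design, documented defaults)
    n_planted_pairs: int = 10
    loading: float = 0.8                # |pathway loading| of member genes
    weibull_shape: float = 1.2
    cluster_beta: float = 0.25          # log HR of subtype B vs A

    def validate(self) -> None:
        if self.n_sets * self.set_size > self.n_genes:
            raise ValueError("n_sets * set_size must not exceed n_genes")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples < 2 or self.n_genes < 2:
            raise ValueError("need at least 2 samples and 2 genes")


@dataclass
class SyntheticTruth:
    """Planted structure shared across cohorts plus per-cohort latents."""

    pathway_loadings: pd.DataFrame      # genes x sets
    subtype_labels: pd.Series           # per sample, in {"A", "B"}
    planted_pairs: list[tuple[str, str]]
    de_genes: list[str]                 # genes with a true subtype shift
    activities: pd.DataFrame            # samples x sets

    @property
    def gene_sets(self) -> dict[str, list[str]]:
        """Membership view of the loading matrix (nonzero loading = member)."""
        L = self.pathway_loadings
        return {s: list(L.index[L[s] != 0]) for s in L.columns}

    def to_json(self, path) -> None:
        payload = {
            "planted_pairs": self.planted_pairs,
            "de_genes": self.de_genes,
            "subtype_labels": self.subtype_labels.to_dict(),
            "gene_sets": self.gene_sets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _gene_structure(spec: CohortSpec, rng: np.random.Generator):
    genes = [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]
    sets = _set_names(spec.n_sets)
    L = pd.DataFrame(0.0, index=genes, columns=sets)
    for k, s in enumerate(sets):
        members = genes[k * spec.set_size:(k + 1) * spec.set_size]
        # predominantly positive loadings so activity shifts move the
        # set-level enrichment score; the negative minority provides the
        # anti-correlated partners the planted pairs are built from
        n_neg = max(1, spec.set_size // 4)
        L.loc[members[:-n_neg], s] = spec.loading
        L.loc[members[-n_neg:], s] = -spec.loading
    # subtype shift acts on the first half of the sets
    shifted = sets[: max(1, spec.n_sets // 2)]
    de_genes = sorted(L.index[(L[shifted] != 0).any(axis=1)])
    # planted pairs: opposite-sign genes inside the same set, spread over sets
    pairs: list[tuple[str, str]] = []
    k = 0
    while len(pairs) < spec.n_planted_pairs:
        s = sets[k % spec.n_sets]
        pos = list(L.index[L[s] > 0])
        neg = list(L.index[L[s] < 0])
        i = k // spec.n_sets
        if i < min(len(pos), len(neg)):
            pairs.append((pos[i], neg[i]))
        k += 1
        if k > spec.n_sets * spec.set_size:
            break
    return genes, sets, L, de_genes, pairs, shifted


def _censoring_rate(event_times: np.ndarray, target: float) -> float:
    """Exponential-censoring rate giving E[fraction censored] = target."""
    if target <= 0:
        return 0.0

    def frac(log_r):
        r = np.exp(log_r)
        return float(np.mean(1.0 - np.exp(-r * event_times))) - target

    return float(np.exp(brentq(frac, -20.0, 20.0)))


def planted_pair_score(expr: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.Series:
    """Integer count of planted pairs with E(first) > E(second), per sample."""
    vals = np.zeros(expr.shape[1], dtype=int)
    for a, b in pairs:
        vals += (expr.loc[a].to_numpy() > expr.loc[b].to_numpy()).astype(int)
    return pd.Series(vals, index=expr.columns, name="planted_pair_score")


def generate_cohort(spec: CohortSpec, truth: SyntheticTruth | None = None,
                    sample_prefix: str = "S"):
    """Generate one bulk cohort: (expression log2, survival table, truth).

    If ``truth`` is supplied, its gene-level structure (loadings, planted
    pairs, DE genes) is reused so cohorts share a gene universe and signal;
    per-sample latents (subtypes, activities, survival) are drawn fresh.
    Deterministic: the same spec (including seed) gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if truth is None:
        genes, sets, L, de_genes, pairs, shifted = _gene_structure(spec, rng)
    else:
        L = truth.pathway_loadings
        if L.shape != (spec.n_genes, spec.n_sets):
            raise ValueError(
                f"supplied truth has loading shape {L.shape}, spec expects "
                f"({spec.n_genes}, {spec.n_sets})")
        genes, sets = list(L.index), list(L.columns)
        de_genes, pairs = truth.de_genes, truth.planted_pairs
        shifted = sets[: max(1, spec.n_sets // 2)]

    samples = [f"{sample_prefix}{i:05d}" for i in range(1, spec.n_samples + 1)]
    labels = pd.Series(rng.choice(["A", "B"], size=spec.n_samples), index=samples)
    if labels.nunique() < 2:  # tiny cohorts: force both subtypes present
        labels.iloc[0] = "A"
        labels.iloc[-1] = "B"
    a = rng.standard_normal((spec.n_samples, spec.n_sets))
    a[:, [sets.index(s) for s in shifted]] += (
        spec.cluster_shift * (labels.to_numpy() == "B")[:, None])
    activities = pd.DataFrame(a, index=samples, columns=sets)

    mu = rng.uniform(2.0, 9.0, size=spec.n_genes)
    # planted-pair partners share a baseline mean so the binary indicator
    # responds to pathway activity rather than to a fixed offset between
    # two unrelated abundance levels
    gene_idx = {g: i for i, g in enumerate(genes)}
    for gp, gn in pairs:
        mu[gene_idx[gn]] = mu[gene_idx[gp]]
    X = (mu[:, None] + L.to_numpy() @ a.T
         + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples)))
    expr = pd.DataFrame(X, index=genes, columns=samples)

    score = planted_pair_score(expr, pairs).to_numpy().astype(float)
    sd = score.std()
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    lp = spec.pair_beta * z + spec.cluster_beta * (labels.to_numpy() == "B")

    shape = spec.weibull_shape
    lam = spec.baseline_hazard_scale / np.log(2.0) ** (1.0 / shape)
    u = rng.uniform(size=spec.n_samples)
    t_event = lam * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    rate = _censoring_rate(t_event, spec.censor_rate)
    if rate > 0:
        c = rng.exponential(1.0 / rate, size=spec.n_samples)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(spec.n_samples, dtype=int)
    survival = pd.DataFrame(
        {"time_months": time, "event": event}, index=pd.Index(samples, name="sample"))

    out_truth = SyntheticTruth(
        pathway_loadings=L, subtype_labels=labels, planted_pairs=list(pairs),
        de_genes=list(de_genes), activities=activities)
    return expr, survival, out_truth


def linear_view(expr_log2: pd.DataFrame) -> pd.DataFrame:
    """TPM-like linear-scale view of a log2(TPM+1) matrix."""
    return (2.0 ** expr_log2 - 1.0).clip(lower=0.0)


def generate_single_cell(spec: CohortSpec, n_cell_types: int = 3,
                         cells_per_type: int = 200,
                         overexpression_fold: float = 5.0):
    """Sparse single-cell counts where each cell type over-expresses one set.

    Returns (counts genes x cells, cell_type labels naming the designated
    set).  ``overexpression_fold = 1`` yields a structureless null matrix.
    """
    spec.validate()
    if spec.n_sets < 2:
        raise ValueError("single-cell generation needs n_sets >= 2")
    if n_cell_types > spec.n_sets:
        raise ValueError("n_cell_types cannot exceed n_sets")
    rng = np.random.default_rng(spec.seed)
    genes, sets, L, *_ = _gene_structure(spec, rng)
    designated = sets[:n_cell_types]
    base = rng.uniform(0.05, 0.8, size=spec.n_genes)
    cols, labels = [], []
    counts = np.zeros((spec.n_genes, n_cell_types * cells_per_type), dtype=np.int32)
    j = 0
    for s in designated:
        member = (L[s] != 0).to_numpy()
        lam = np.where(member, base * overexpression_fold, base)
        for c in range(cells_per_type):
            counts[:, j] = rng.poisson(lam)
            cols.append(f"{s}_cell{c + 1:04d}")
            labels.append(s)
            j += 1
    counts_df = pd.DataFrame(counts, index=genes, columns=cols)
    return counts_df, pd.Series(labels, index=cols, name="cell_type")


def generate_gene_cohort(n_samples: int = 200, n_null_genes: int = 55,
                         planted_betas=(1.0, 1.0, 1.0, 1.0, 1.0),
                         censor_rate: float = 0.3, seed: int = 0,
                         baseline_scale: float = 24.0,
                         weibull_shape: float = 1.2,
                         sample_prefix: str = "S"):
    """Gene-level prognostic cohort for the feature-screen benchmarks.

    Planted genes (first ``len(planted_betas)``) carry additive per-SD log
    hazard ratios; the remaining genes are independent noise.  Returns
    (expression genes x samples on a log2-like scale, survival table,
    planted gene names).
    """
    rng = np.random.default_rng(seed)
    k = len(planted_betas)
    genes = ([f"PG{i + 1:03d}" for i in range(k)]
             + [f"NG{i + 1:03d}" for i in range(n_null_genes)])
    samples = [f"{sample_prefix}{i:05d}" for i in range(1, n_samples + 1)]
    Z = rng.standard_normal((len(genes), n_samples))
    mu = rng.uniform(3.0, 8.0, size=len(genes))
    expr = pd.DataFrame(Z + mu[:, None], index=genes, columns=samples)
    lp = np.asarray(planted_betas) @ Z[:k]
    lam = baseline_scale / np.log(2.0) ** (1.0 / weibull_shape)
    u = rng.uniform(size=n_samples)
    t_event = lam * (-np.log(u) / np.exp(lp)) ** (1.0 / weibull_shape)
    rate = _censoring_rate(t_event, censor_rate)
    if rate > 0:
        c = rng.exponential(1.0 / rate, size=n_samples)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(n_samples, dtype=int)
    survival = pd.DataFrame({"time_months": time, "event": event},
                            index=pd.Index(samples, name="sample"))
    return expr, survival, genes[:k]


def spec_to_dict(spec: CohortSpec) -> dict:
    return asdict(spec)
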