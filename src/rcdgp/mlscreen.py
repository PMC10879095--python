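"""The four-step therapeutic-target screen with a 14-variant consensus vote.

Step 1: genes with univariate Cox p < alpha in every cohort.
Step 2: the three-way intersection of rank-sum DEG lists (tumour A vs normal,
        tumour B vs normal, tumour A vs tumour B).
Step 3: intersection with the RCD-related gene list.
Step 4: fourteen feature-selection variants vote on the surviving genes —
        Lasso, elastic net at alpha = 0.1..0.9 (nine variants), componentwise
        Cox likelihood boosting, Boruta with survival-forest importance,
        random survival forest permutation importance, and Cox-objective
        XGBoost gain — and genes selected by at least ``threshold`` variants
        in *both* cohorts pass.

The componentwise Cox boosting is implemented here from its defining recipe:
each step updates the single covariate maximising the penalised score
statistic U^2/(I + lambda), with lambda = (1/nu - 1) * n_events and the step
count chosen by cross-validated partial log-likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from ._cox import CoxData, componentwise_scores, cox_newton_univariate, partial_loglik
from .subtype import wilcoxon_deg

logger = logging.getLogger(__name__)

__all__ = ["VARIANTS", "SelectionVoteTable", "prognostic_genes",
           "critical_degs", "screen_input_genes", "method_select",
           "consensus_screen", "consensus_vote", "coxboost_select",
           "boruta_select"]

#: the 14 method variants: Lasso, 9 elastic nets, and the four others
VARIANTS = (["lasso"]
            + [f"enet_{a:.1f}" for a in np.arange(0.1, 0.95, 0.1)]
            + ["coxboost", "boruta", "rsf", "xgboost"])


# ---------------------------------------------------------------- steps 1-3

def prognostic_genes(cohorts, alpha: float = 0.05) -> list[str]:
    """Genes with univariate Cox Wald p < alpha in every usable cohort.

    ``cohorts`` is a sequence of (expression genes x samples, survival table)
    tuples; cohorts with fewer than 10 events are excluded with a warning.
    """
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("need at least one cohort")
    sets = []
    for i, (expr, surv) in enumerate(cohorts):
        common = expr.columns.intersection(surv.index)
        sv = surv.loc[common]
        if int(sv["event"].sum()) < 10:
            logger.warning("cohort %d has < 10 events; excluded from the "
                           "prognostic screen", i)
            continue
        X = expr[common].to_numpy(dtype=float)
        sd = X.std(axis=1, keepdims=True)
        Xs = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
        res = cox_newton_univariate(Xs, sv["time_months"].to_numpy(),
                                    sv["event"].to_numpy())
        sets.append(set(np.asarray(expr.index)[res["p"] < alpha]))
    if not sets:
        raise ValueError("no cohort had enough events for the screen")
    return sorted(set.intersection(*sets))


def critical_degs(tumorA: pd.DataFrame, tumorB: pd.DataFrame,
                  normal: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Intersection of the three pairwise rank-sum DEG lists (p < alpha)."""
    out = None
    for x, y in ((tumorA, normal), (tumorB, normal), (tumorA, tumorB)):
        tab = wilcoxon_deg(x, y)
        degs = set(tab.index[tab["p_value"] < alpha])
        out = degs if out is None else out & degs
    return sorted(out)


def screen_input_genes(critical, prognostic, rcd_related) -> list[str]:
    """Three-way intersection feeding the consensus vote."""
    a, b, c = set(critical), set(prognostic), set(rcd_related)
    if not (a and b and c):
        raise ValueError("all three input gene lists must be nonempty")
    out = sorted(a & b & c)
    if not out:
        raise ValueError(
            "screen funnel is empty: "
            f"|DEG|={len(a)}, |prognostic|={len(b)}, |RCD|={len(c)}")
    return out


# ------------------------------------------------------------- the variants

def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, keepdims=True)
    return (X - X.mean(axis=0, keepdims=True)) / np.where(sd > 0, sd, 1.0)


def _surv_y(survival: pd.DataFrame):
    return Surv.from_arrays(event=survival["event"].to_numpy().astype(bool),
                            time=survival["time_months"].to_numpy())


def _coxnet_select(X, survival, l1_ratio, seed, cv=5, n_alphas=25) -> set[int]:
    """Nonzero coefficients at the cross-validated Coxnet penalty."""
    y = _surv_y(survival)
    base = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=n_alphas,
                                  alpha_min_ratio=0.05)
    base.fit(X, y)
    alphas = base.alphas_
    kf = KFold(n_splits=cv, shuffle=True, random_state=seed)
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for tr, te in kf.split(X):
        try:
            m = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas)
            m.fit(X[tr], y[tr])
        except Exception:  # degenerate fold
            continue
        ev = survival["event"].to_numpy().astype(bool)[te]
        tm = survival["time_months"].to_numpy()[te]
        if ev.sum() < 2:
            continue
        for ai, alpha in enumerate(m.alphas_):
            risk = m.predict(X[te], alpha=alpha)
            if np.std(risk) == 0:
                continue
            c = concordance_index_censored(ev, tm, risk)[0]
            scores[ai] += c
            counts[ai] += 1
    usable = counts > 0
    if not usable.any():
        return set()
    best = np.flatnonzero(usable)[int(np.argmax(scores[usable] / counts[usable]))]
    coefs = base.coef_[:, best]
    return set(np.flatnonzero(coefs != 0))


def coxboost_select(X, survival, nu: float = 0.1, max_steps: int = 500,
                    cv: int = 10, seed: int = 0, return_path: bool = False):
    """Componentwise Cox likelihood boosting; returns selected column indices.

    Each step updates the covariate maximising the penalised score statistic
    U_j^2 / (I_j + lambda) with lambda = (1/nu - 1) * n_events(train); the
    number of steps is chosen by ``cv``-fold cross-validated test partial
    log-likelihood (0 steps allowed, giving an empty selection).
    """
    time = survival["time_months"].to_numpy()
    event = survival["event"].to_numpy()
    n, p = X.shape

    def _boost(Xtr, ttr, etr, steps):
        cd = CoxData.from_arrays(ttr, etr)
        Xs = Xtr[cd.order].T                    # (p, n) sorted order
        lam = (1.0 / nu - 1.0) * etr.sum()
        beta = np.zeros(p)
        eta = np.zeros(len(ttr))
        path = np.zeros((steps + 1, p))
        for step in range(1, steps + 1):
            U, I = componentwise_scores(eta, Xs, cd)
            crit = U * U / (I + lam)
            j = int(np.argmax(crit))
            db = U[j] / (I[j] + lam)
            beta[j] += db
            eta = eta + db * Xs[j]
            path[step] = beta
        return path

    kf = KFold(n_splits=cv, shuffle=True, random_state=seed)
    cv_ll = np.zeros(max_steps + 1)
    folds = 0
    for tr, te in kf.split(X):
        if event[te].sum() == 0 or event[tr].sum() == 0:
            continue
        path = _boost(X[tr], time[tr], event[tr], max_steps)
        cd_te = CoxData.from_arrays(time[te], event[te])
        for s in range(max_steps + 1):
            cv_ll[s] += partial_loglik(X[te] @ path[s], time[te], event[te], cd_te)
        folds += 1
    best_steps = int(np.argmax(cv_ll)) if folds else 0
    path = _boost(X, time, event, max(best_steps, 1))
    beta = path[best_steps]
    selected = set(np.flatnonzero(beta != 0)) if best_steps > 0 else set()
    if return_path:
        return selected, path, best_steps
    return selected


def _perm_importance(model, X, time, event, rng, n_repeats=1):
    """Permutation importance of each column: drop in Harrell concordance.

    Evaluate on data the model was *not* fitted on: with tree ensembles,
    training-set importance is positive for almost every feature the trees
    touched, which would make an 'importance > 0' rule vacuous.
    """
    ee = event.astype(bool)
    base_risk = model.predict(X)
    if np.std(base_risk) == 0 or ee.sum() < 2:
        return np.zeros(X.shape[1])
    base = concordance_index_censored(ee, time, base_risk)[0]
    imp = np.zeros(X.shape[1])
    n = X.shape[0]
    for j in range(X.shape[1]):
        acc = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            risk = model.predict(Xp)
            acc += base - concordance_index_censored(ee, time, risk)[0]
        imp[j] = acc / n_repeats
    return imp


def _holdout_split(n, rng, frac=0.3):
    idx = rng.permutation(n)
    n_te = max(20, int(round(frac * n)))
    return idx[n_te:], idx[:n_te]


def rsf_select(X, survival, seed, n_estimators: int = 1000,
               n_repeats: int = 3, min_samples_leaf: int = 15) -> set[int]:
    """Random survival forest; held-out permutation importance > 0 selects."""
    rng = np.random.default_rng(seed)
    time = survival["time_months"].to_numpy()
    event = survival["event"].to_numpy()
    tr, te = _holdout_split(X.shape[0], rng)
    rsf = RandomSurvivalForest(n_estimators=n_estimators, n_jobs=1,
                               min_samples_leaf=min_samples_leaf,
                               random_state=seed)
    rsf.fit(X[tr], _surv_y(survival.iloc[tr]))
    imp = _perm_importance(rsf, X[te], time[te], event[te], rng,
                           n_repeats=n_repeats)
    return set(np.flatnonzero(imp > 0))


def boruta_select(X, survival, seed, max_iter: int = 100, alpha: float = 0.01,
                  n_estimators: int = 100, min_hits_frac: float | None = None) -> set[int]:
    """Boruta with survival-forest importance and shadow features.

    Each iteration appends a column-permuted shadow copy of X, fits a
    survival forest, and scores a 'hit' for every real feature whose
    permutation importance exceeds the maximum shadow importance.  Features
    are confirmed/rejected by a two-sided binomial test at ``alpha``;
    tentative features at exhaustion are not selected.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    time = survival["time_months"].to_numpy()
    event = survival["event"].to_numpy()
    hits = np.zeros(p, dtype=int)
    decided = np.zeros(p, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
    trials = 0
    for it in range(max_iter):
        shadow = X.copy()
        for j in range(p):
            shadow[:, j] = shadow[rng.permutation(n), j]
        Xa = np.hstack([X, shadow])
        tr, te = _holdout_split(n, rng)
        forest = RandomSurvivalForest(n_estimators=n_estimators, n_jobs=1,
                                      min_samples_leaf=15,
                                      random_state=seed + it)
        forest.fit(Xa[tr], _surv_y(survival.iloc[tr]))
        imp = _perm_importance(forest, Xa[te], time[te], event[te], rng)
        thresh = imp[p:].max()
        hits += (imp[:p] > thresh).astype(int)
        trials += 1
        if trials >= 5:
            for j in np.flatnonzero(decided == 0):
                p_hi = stats.binom.sf(hits[j] - 1, trials, 0.5)
                p_lo = stats.binom.cdf(hits[j], trials, 0.5)
                if p_hi < alpha / 2:
                    decided[j] = 1
                elif p_lo < alpha / 2:
                    decided[j] = -1
        if np.all(decided != 0):
            break
    return set(np.flatnonzero(decided == 1))


def xgboost_select(X, survival, seed, num_boost_round: int = 200,
                   nfold: int = 10, early_stopping_rounds: int = 20,
                   feature_names=None) -> set[int]:
    """Cox-objective gradient boosting; features with positive gain."""
    import xgboost as xgb

    time = survival["time_months"].to_numpy()
    event = survival["event"].to_numpy()
    label = np.where(event > 0, time, -time)
    names = [f"f{j}" for j in range(X.shape[1])]
    dtrain = xgb.DMatrix(X, label=label, feature_names=names)
    params = {"objective": "survival:cox", "eta": 0.05, "max_depth": 2,
              "subsample": 0.8, "seed": int(seed), "nthread": 1}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cvres = xgb.cv(params, dtrain, num_boost_round=num_boost_round,
                       nfold=nfold, early_stopping_rounds=early_stopping_rounds,
                       seed=int(seed), shuffle=True)
        best = len(cvres)
        bst = xgb.train(params, dtrain, num_boost_round=max(best, 1))
    gains = bst.get_score(importance_type="gain")
    return {int(k[1:]) for k, v in gains.items() if v > 0}


def method_select(variant: str, X: pd.DataFrame, survival: pd.DataFrame,
                  seed: int = 0, **params) -> set[str]:
    """Run one selection variant; returns the selected gene names.

    ``X`` is samples x genes; it is standardised per gene internally.
    A variant that fails records an empty selection rather than aborting.
    """
    if variant not in VARIANTS:
        raise KeyError(f"unknown variant {variant!r}; one of {VARIANTS}")
    genes = list(X.columns)
    common = X.index.intersection(survival.index)
    Xs = _standardize(X.loc[common].to_numpy(dtype=float))
    surv = survival.loc[common]
    if int(surv["event"].sum()) < 10:
        raise ValueError("need at least 10 events for the method screen")
    try:
        if variant == "lasso":
            idx = _coxnet_select(Xs, surv, l1_ratio=1.0, seed=seed, **params)
        elif variant.startswith("enet_"):
            idx = _coxnet_select(Xs, surv, l1_ratio=float(variant[5:]),
                                 seed=seed, **params)
        elif variant == "coxboost":
            idx = coxboost_select(Xs, surv, seed=seed, **params)
        elif variant == "rsf":
            idx = rsf_select(Xs, surv, seed=seed, **params)
        elif variant == "boruta":
            idx = boruta_select(Xs, surv, seed=seed, **params)
        elif variant == "xgboost":
            idx = xgboost_select(Xs, surv, seed=seed, **params)
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("variant %s failed (%s); empty selection", variant, exc)
        idx = set()
    return {genes[j] for j in idx}


@dataclass
class SelectionVoteTable:
    """Gene x variant boolean selections with per-gene vote counts."""

    votes: pd.DataFrame                  # genes x variants, bool
    seeds: dict[str, int] = field(default_factory=dict)
    params: dict[str, dict] = field(default_factory=dict)

    @property
    def counts(self) -> pd.Series:
        return self.votes.sum(axis=1).rename("votes")

    def to_tsv(self, path) -> None:
        out = self.votes.astype(int)
        out["votes"] = self.counts
        out.to_csv(path, sep="\t")


def consensus_screen(X: pd.DataFrame, survival: pd.DataFrame, seed: int = 0,
                     variant_params: dict | None = None) -> SelectionVoteTable:
    """Run all 14 variants on one cohort and tabulate the votes."""
    variant_params = variant_params or {}
    votes = pd.DataFrame(False, index=list(X.columns), columns=VARIANTS)
    seeds, params_used = {}, {}
    for vi, variant in enumerate(VARIANTS):
        vseed = (seed * 1009 + vi * 9176) % (2 ** 31 - 1)
        p = dict(variant_params.get(variant, {}))
        selected = method_select(variant, X, survival, seed=vseed, **p)
        votes.loc[sorted(selected), variant] = True
        seeds[variant] = vseed
        params_used[variant] = p
    return SelectionVoteTable(votes=votes, seeds=seeds, params=params_used)


def consensus_vote(votesA: SelectionVoteTable, votesB: SelectionVoteTable,
                   threshold: int = 10) -> list[str]:
    """Genes reaching >= threshold variant votes in both cohorts."""
    ca, cb = votesA.counts, votesB.counts
    common = ca.index.intersection(cb.index)
    keep = (ca.loc[common] >= threshold) & (cb.loc[common] >= threshold)
    return sorted(common[keep])
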