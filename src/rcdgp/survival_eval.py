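"""Risk stratification and prognostic evaluation.

* maximally selected rank statistics to dichotomise a continuous risk score
  (the maximum standardized two-sample log-rank statistic over admissible
  cutpoints, with a minimum group proportion);
* Kaplan-Meier curves and the log-rank test (via lifelines);
* uni-/multivariate Cox proportional hazards (via lifelines, Efron ties);
* Harrell's C-index and IPCW cumulative/dynamic AUC at fixed horizons
  (via scikit-survival);
* inverse-variance fixed-effect and DerSimonian-Laird random-effects
  meta-analysis of per-cohort log hazard ratios.

The cutpoint-selected log-rank p-value is reported as-is alongside a
Lausen-Schumacher-type corrected p-value that accounts for the maximal
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv

logger = logging.getLogger(__name__)

__all__ = ["CutpointResult", "max_sel_cutpoint", "logrank_test", "km_curves",
           "cox_model", "concordance_and_auc", "MetaResult", "meta_hr",
           "CollinearityError"]


class CollinearityError(ValueError):
    """Raised when multivariate Cox covariates are (near-)collinear."""


@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float                 # max standardized log-rank statistic
    labels: pd.Series                # 'high' (score > cutpoint) / 'low'
    minprop: float
    p_selected: float                # naive log-rank p at the chosen split
    p_corrected: float               # maximal-selection-corrected p
    candidates: pd.DataFrame = field(repr=False, default=None)


def _logrank_stats_for_splits(score: np.ndarray, time: np.ndarray,
                              event: np.ndarray, cuts: np.ndarray):
    """Standardized two-sample log-rank statistic for each cut (group: > cut)."""
    order = np.argsort(-time, kind="stable")
    t, e, s = time[order], event[order], score[order]
    ev_pos = np.flatnonzero(e)
    uniq, starts = np.unique(-t[ev_pos], return_index=True)
    starts = np.sort(starts)
    d = np.diff(np.append(starts, len(ev_pos)))
    risk_end = np.searchsorted(-t, uniq, side="right")
    G = (s[None, :] > cuts[:, None]).astype(float)      # (C, n) group-1 mask
    cum = np.cumsum(G, axis=1)
    n1 = cum[:, risk_end - 1]                            # (C, groups)
    nr = risk_end.astype(float)
    d1 = np.add.reduceat(G[:, ev_pos], starts, axis=1)
    dd = d.astype(float)
    U = (d1 - dd * n1 / nr).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        V = np.where(nr > 1,
                     dd * (n1 / nr) * (1 - n1 / nr) * (nr - dd) / (nr - 1),
                     0.0).sum(axis=1)
    stat = np.where(V > 0, np.abs(U) / np.sqrt(np.maximum(V, 1e-300)), 0.0)
    return stat


def _lausen_schumacher_p(b: float, q1: float, q2: float) -> float:
    """Approximate p-value of the maximally selected log-rank statistic."""
    if b <= 0:
        return 1.0
    phi = stats.norm.pdf(b)
    log_term = np.log((q2 * (1 - q1)) / (q1 * (1 - q2)))
    p = phi * (b - 1.0 / b) * log_term + 4.0 * phi / b
    return float(min(max(p, 2.0 * stats.norm.sf(b)), 1.0))


def max_sel_cutpoint(score: pd.Series, survival: pd.DataFrame,
                     minprop: float = 0.1) -> CutpointResult:
    """Dichotomise a risk score at the maximally selected log-rank statistic.

    Candidate cutpoints are midpoints between consecutive distinct score
    values such that both groups keep at least ``minprop`` of the samples.
    Ties in the statistic resolve to the lower cutpoint.
    """
    common = score.index.intersection(survival.index)
    s = score.loc[common].to_numpy(dtype=float)
    time = survival.loc[common, "time_months"].to_numpy(dtype=float)
    event = survival.loc[common, "event"].to_numpy(dtype=float)
    n = len(common)
    vals = np.unique(s)
    if len(vals) < 2:
        raise ValueError("score must take at least 2 distinct values")
    mids = (vals[:-1] + vals[1:]) / 2.0
    lo_counts = np.searchsorted(np.sort(s), mids, side="right")
    min_n = max(1, int(np.ceil(minprop * n)))
    ok = (lo_counts >= min_n) & ((n - lo_counts) >= min_n)
    if not ok.any():
        raise ValueError("no admissible split satisfies the minprop bound")
    cuts = mids[ok]
    stat = _logrank_stats_for_splits(s, time, event, cuts)
    best = int(np.argmax(stat))  # argmax returns the first (lowest) maximiser
    cut = float(cuts[best])
    b = float(stat[best])
    labels = pd.Series(np.where(s > cut, "high", "low"), index=common,
                       name="risk_group")
    chi2, p_naive = logrank_test(labels, survival.loc[common])
    q1 = lo_counts[ok][best] / n
    p_corr = _lausen_schumacher_p(b, min(q1, 1 - q1), max(q1, 1 - q1))
    cand = pd.DataFrame({"cutpoint": cuts, "statistic": stat})
    return CutpointResult(cutpoint=cut, statistic=b, labels=labels,
                          minprop=minprop, p_selected=float(p_naive),
                          p_corrected=p_corr, candidates=cand)


def logrank_test(groups: pd.Series, survival: pd.DataFrame):
    """k-sample log-rank test; returns (chi2, p)."""
    common = groups.index.intersection(survival.index)
    g = groups.loc[common]
    if g.nunique() < 2:
        raise ValueError("need at least 2 groups with observations")
    res = multivariate_logrank_test(
        survival.loc[common, "time_months"], g, survival.loc[common, "event"])
    return float(res.test_statistic), float(res.p_value)


def km_curves(groups: pd.Series, survival: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier survival curve (with Greenwood-based CI) per group."""
    out = {}
    common = groups.index.intersection(survival.index)
    for label, members in groups.loc[common].groupby(groups.loc[common]).groups.items():
        if len(members) == 0:
            raise ValueError(f"group {label!r} has no observations")
        km = KaplanMeierFitter(label=str(label))
        km.fit(survival.loc[members, "time_months"],
               survival.loc[members, "event"])
        df = km.survival_function_.join(km.confidence_interval_)
        df.columns = ["survival", "ci_lower", "ci_upper"]
        out[str(label)] = df
    return out


def cox_model(covariates: pd.DataFrame, survival: pd.DataFrame,
              multivariate: bool = True) -> pd.DataFrame:
    """Cox PH fit(s); per-covariate HR, 95% CI and Wald p.

    ``multivariate=False`` fits each covariate in its own univariate model.
    Exactly collinear covariate pairs raise :class:`CollinearityError`.
    """
    common = covariates.index.intersection(survival.index)
    cov = covariates.loc[common]
    surv = survival.loc[common]
    if int(surv["event"].sum()) <= cov.shape[1] and multivariate:
        raise ValueError("events must exceed the number of covariates")
    if multivariate and cov.shape[1] > 1:
        corr = np.corrcoef(cov.to_numpy(), rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        if np.any(np.abs(corr[iu]) > 0.9999):
            raise CollinearityError("covariates are (near-)exactly collinear")
    frames = [cov] if multivariate else [cov[[c]] for c in cov.columns]
    rows = []
    for frame in frames:
        df = frame.join(surv[["time_months", "event"]])
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time_months", event_col="event")
        summ = cph.summary
        for name in frame.columns:
            rows.append({
                "covariate": name,
                "hazard_ratio": float(summ.loc[name, "exp(coef)"]),
                "ci_lower": float(summ.loc[name, "exp(coef) lower 95%"]),
                "ci_upper": float(summ.loc[name, "exp(coef) upper 95%"]),
                "log_hr": float(summ.loc[name, "coef"]),
                "log_hr_se": float(summ.loc[name, "se(coef)"]),
                "p_value": float(summ.loc[name, "p"]),
                "model": "multivariate" if multivariate else "univariate",
            })
    return pd.DataFrame(rows).set_index("covariate")


def concordance_and_auc(score: pd.Series, survival: pd.DataFrame,
                        horizons=(12.0, 36.0, 60.0)) -> dict:
    """Harrell C-index plus IPCW cumulative/dynamic AUC at fixed horizons.

    Horizons beyond (or at) the observed follow-up range are flagged and
    their AUC omitted (None).  With no censoring the IPCW weights are all 1.
    """
    common = score.index.intersection(survival.index)
    s = score.loc[common].to_numpy(dtype=float)
    time = survival.loc[common, "time_months"].to_numpy(dtype=float)
    event = survival.loc[common, "event"].to_numpy(dtype=bool)
    cindex = float(concordance_index_censored(event, time, s)[0])
    y = Surv.from_arrays(event=event, time=time)
    aucs: dict[float, float | None] = {}
    t_max = time[event].max() if event.any() else 0.0
    t_min = time.min()
    for h in horizons:
        if not (t_min < h < t_max) or not (event & (time <= h)).any():
            logger.warning("horizon %s months outside usable follow-up; AUC omitted", h)
            aucs[float(h)] = None
            continue
        a, _ = cumulative_dynamic_auc(y, y, s, [h])
        aucs[float(h)] = float(a[0])
    return {"c_index": cindex, "auc": aucs, "n": int(len(common)),
            "n_events": int(event.sum())}


@dataclass
class MetaResult:
    cohorts: list[str]
    log_hr: np.ndarray
    se: np.ndarray
    fixed_log_hr: float
    fixed_se: float
    random_log_hr: float
    random_se: float
    tau2: float
    Q: float
    I2: float                        # percent
    df: int

    @property
    def fixed_hr(self) -> float:
        return float(np.exp(self.fixed_log_hr))

    @property
    def random_hr(self) -> float:
        return float(np.exp(self.random_log_hr))

    def to_frame(self) -> pd.DataFrame:
        w_f = 1.0 / self.se ** 2
        w_r = 1.0 / (self.se ** 2 + self.tau2)
        return pd.DataFrame({
            "cohort": self.cohorts, "log_hr": self.log_hr, "se": self.se,
            "weight_fixed": w_f / w_f.sum(), "weight_random": w_r / w_r.sum(),
        }).set_index("cohort")


def meta_hr(log_hrs, ses, cohorts=None) -> MetaResult:
    """Fixed-effect (inverse variance) and DerSimonian-Laird pooling."""
    theta = np.asarray(log_hrs, dtype=float)
    se = np.asarray(ses, dtype=float)
    if theta.ndim != 1 or theta.shape != se.shape or len(theta) == 0:
        raise ValueError("log_hrs and ses must be equal-length 1-D sequences")
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("standard errors must be positive and finite")
    names = list(cohorts) if cohorts is not None else [
        f"cohort_{i + 1}" for i in range(len(theta))]
    w = 1.0 / se ** 2
    fixed = float((w * theta).sum() / w.sum())
    fixed_se = float(np.sqrt(1.0 / w.sum()))
    df = len(theta) - 1
    Q = float((w * (theta - fixed) ** 2).sum())
    if df > 0:
        c = w.sum() - (w ** 2).sum() / w.sum()
        tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
        I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    else:
        tau2, I2 = 0.0, 0.0
    wr = 1.0 / (se ** 2 + tau2)
    random = float((wr * theta).sum() / wr.sum())
    random_se = float(np.sqrt(1.0 / wr.sum()))
    return MetaResult(cohorts=names, log_hr=theta, se=se,
                      fixed_log_hr=fixed, fixed_se=fixed_se,
                      random_log_hr=random, random_se=random_se,
                      tau2=tau2, Q=Q, I2=I2, df=df)
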