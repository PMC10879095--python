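"""Vectorised Cox partial-likelihood machinery (Efron tie handling).

The gene-pair screen fits ~10^4-10^5 single-covariate Cox models per cohort,
which is far too many for a general-purpose fitter.  This module implements
the one-dimensional Newton fit directly on the Efron partial likelihood,
vectorised across covariates: all covariates share the risk-set structure of
the cohort, so each Newton sweep is a handful of cumulative sums over a
(covariates x samples) array.

Also provides the building blocks for componentwise likelihood boosting
(per-covariate score/information at a fixed linear predictor, and the
penalised partial log-likelihood itself).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CoxData",
    "cox_newton_univariate",
    "componentwise_scores",
    "partial_loglik",
]

_MAX_BETA = 15.0  # |beta| beyond this is treated as monotone likelihood


@dataclass
class CoxData:
    """Pre-sorted survival data with Efron tie-group bookkeeping.

    Samples are sorted by *descending* time so that the risk set at any event
    time is a prefix of the array and risk-set sums are cumulative sums.
    """

    order: np.ndarray          # descending-time ordering of the input samples
    time: np.ndarray           # sorted descending
    event: np.ndarray          # bool, sorted like `time`
    risk_end: np.ndarray       # per tie-group: prefix length of the risk set
    grp_event_pos: np.ndarray  # concatenated positions (in sorted order) of events, grouped by tie group
    grp_start: np.ndarray      # start offsets into grp_event_pos per group
    d: np.ndarray              # events per tie group
    n_events: int

    @classmethod
    def from_arrays(cls, time, event) -> "CoxData":
        time = np.asarray(time, dtype=float)
        event = np.asarray(event).astype(bool)
        if time.shape != event.shape or time.ndim != 1:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if event.sum() == 0:
            raise ValueError("no events in survival data; Cox fit undefined")
        order = np.lexsort((~event, -time))  # desc time; within ties events last is irrelevant
        t = time[order]
        e = event[order]
        ev_pos = np.flatnonzero(e)
        ev_times = t[ev_pos]
        # tie groups over *event* times, walked in descending order
        uniq, first_idx = np.unique(-ev_times, return_index=True)
        grp_times = -uniq
        grp_start = np.sort(first_idx)
        # events are already ordered by descending time, so grouping is contiguous
        d = np.diff(np.append(grp_start, len(ev_pos)))
        # risk set for event time tau: all samples with time >= tau (a prefix)
        # t is descending -> count of t >= tau via searchsorted on -t
        risk_end = np.searchsorted(-t, -grp_times, side="right")
        return cls(
            order=order,
            time=t,
            event=e,
            risk_end=risk_end,
            grp_event_pos=ev_pos,
            grp_start=grp_start,
            d=d.astype(np.int64),
            n_events=int(e.sum()),
        )

    @property
    def max_d(self) -> int:
        return int(self.d.max())


def _efron_sums(cd: CoxData, W: np.ndarray):
    """Risk-set and tie-group sums of a weight array W (rows x samples, sorted order)."""
    cum = np.cumsum(W, axis=-1)
    S = cum[..., cd.risk_end - 1]                       # (rows, G)
    tie = np.add.reduceat(W[..., cd.grp_event_pos], cd.grp_start, axis=-1)
    return S, tie


def _efron_ll_U_I(cd: CoxData, beta, Xs):
    """Log-likelihood, score and information per row of Xs at per-row beta.

    Xs: (rows, n) covariate values in sorted (descending-time) order.
    """
    b = beta[:, None]
    W = np.exp(b * Xs)
    WX = W * Xs
    WXX = WX * Xs
    S0, s0 = _efron_sums(cd, W)
    S1, s1 = _efron_sums(cd, WX)
    S2, s2 = _efron_sums(cd, WXX)

    x_ev_sum = Xs[:, cd.grp_event_pos].sum(axis=1)
    ll = beta * x_ev_sum
    U = x_ev_sum.copy()
    I = np.zeros_like(beta)
    dmax = cd.max_d
    dd = cd.d.astype(float)
    for l in range(dmax):
        mask = cd.d > l
        frac = np.where(mask, l / dd, 0.0)
        den = S0[:, mask] - frac[mask] * s0[:, mask]
        n1 = S1[:, mask] - frac[mask] * s1[:, mask]
        n2 = S2[:, mask] - frac[mask] * s2[:, mask]
        ll -= np.log(den).sum(axis=1)
        r = n1 / den
        U -= r.sum(axis=1)
        I += (n2 / den - r * r).sum(axis=1)
    return ll, U, I


def cox_newton_univariate(X, time, event, max_iter: int = 40, tol: float = 1e-8,
                          chunk: int = 4096):
    """Single-covariate Cox fits for every row of X, Efron ties, Wald inference.

    Parameters
    ----------
    X : (p, n) array — each row a covariate over the same n samples.
    time, event : survival outcome (event in {0,1}).

    Returns
    -------
    dict of 1-D arrays: ``log_hr``, ``se``, ``p``, ``converged``.
    Non-convergent / monotone-likelihood / constant covariates are flagged
    ``converged=False`` and assigned p = 1 (log_hr = nan).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cd = CoxData.from_arrays(time, event)
    p, n = X.shape
    log_hr = np.full(p, np.nan)
    se = np.full(p, np.nan)
    pval = np.ones(p)
    conv = np.zeros(p, dtype=bool)

    for lo in range(0, p, chunk):
        hi = min(lo + chunk, p)
        Xc = X[lo:hi][:, cd.order]
        rows = Xc.shape[0]
        variable = Xc.std(axis=1) > 0
        beta = np.zeros(rows)
        ok = variable.copy()
        for _ in range(max_iter):
            if not ok.any():
                break
            _, U, I = _efron_ll_U_I(cd, beta, Xc)
            good = ok & (I > 1e-12)
            step = np.zeros(rows)
            step[good] = U[good] / I[good]
            np.clip(step, -2.0, 2.0, out=step)
            beta = np.where(good, beta + step, beta)
            runaway = np.abs(beta) > _MAX_BETA
            ok &= ~runaway
            if np.all(np.abs(step[good]) < tol):
                break
        _, U, I = _efron_ll_U_I(cd, beta, Xc)
        done = variable & (np.abs(beta) <= _MAX_BETA) & (I > 1e-12)
        # converged where the final Newton step would be negligible
        final_step = np.zeros(rows)
        final_step[done] = np.abs(U[done] / I[done])
        done &= final_step < 1e-4
        s = np.full(rows, np.nan)
        s[done] = 1.0 / np.sqrt(I[done])
        z = np.zeros(rows)
        z[done] = beta[done] / s[done]
        pv = np.ones(rows)
        pv[done] = 2.0 * stats.norm.sf(np.abs(z[done]))
        log_hr[lo:hi] = np.where(done, beta, np.nan)
        se[lo:hi] = s
        pval[lo:hi] = pv
        conv[lo:hi] = done
    return {"log_hr": log_hr, "se": se, "p": pval, "converged": conv}


def partial_loglik(eta, time, event, cd: CoxData | None = None) -> float:
    """Efron partial log-likelihood of a fixed linear predictor eta."""
    if cd is None:
        cd = CoxData.from_arrays(time, event)
    eta_s = np.asarray(eta, dtype=float)[cd.order][None, :]
    W = np.exp(eta_s)
    S0, s0 = _efron_sums(cd, W)
    ll = float(eta_s[0, cd.grp_event_pos].sum())
    dd = cd.d.astype(float)
    for l in range(cd.max_d):
        mask = cd.d > l
        frac = l / dd[mask]
        ll -= float(np.log(S0[0, mask] - frac * s0[0, mask]).sum())
    return ll


def componentwise_scores(eta, X_sorted, cd: CoxData):
    """Per-covariate score U_j and information I_j at offset eta (for boosting).

    X_sorted : (p, n) covariates already in ``cd`` sorted order.
    eta : (n,) current linear predictor in sorted order.
    """
    w = np.exp(np.asarray(eta, dtype=float))[None, :]
    WX = w * X_sorted
    WXX = WX * X_sorted
    S0, s0 = _efron_sums(cd, w)
    S1, s1 = _efron_sums(cd, WX)
    S2, s2 = _efron_sums(cd, WXX)
    U = X_sorted[:, cd.grp_event_pos].sum(axis=1)
    I = np.zeros(X_sorted.shape[0])
    dd = cd.d.astype(float)
    for l in range(cd.max_d):
        mask = cd.d > l
        frac = l / dd[mask]
        den = S0[0, mask] - frac * s0[0, mask]
        n1 = S1[:, mask] - frac * s1[:, mask]
        n2 = S2[:, mask] - frac * s2[:, mask]
        r = n1 / den
        U -= r.sum(axis=1)
        I += (n2 / den - r * r).sum(axis=1)
    return U, I
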