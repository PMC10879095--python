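"""Cutpoint selection, log-rank/KM, Cox, concordance/AUC, meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from rcdgp.survival_eval import (CollinearityError, concordance_and_auc,
                                 cox_model, km_curves, logrank_test,
                                 max_sel_cutpoint, meta_hr)
from tests.conftest import weibull_survival


def _surv(times, events, index=None):
    idx = index if index is not None else [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"time_months": times, "event": events},
                        index=pd.Index(idx, name="sample"))


class TestCutpoint:
    def _brute(self, score, surv, minprop=0.1):
        vals = np.sort(score.unique())
        mids = (vals[:-1] + vals[1:]) / 2.0
        n = len(score)
        min_n = max(1, int(np.ceil(minprop * n)))
        best = (None, -1.0)
        for c in mids:
            lo = score <= c
            if lo.sum() < min_n or (~lo).sum() < min_n:
                continue
            res = ll_logrank(surv.loc[lo.index[lo], "time_months"],
                             surv.loc[lo.index[~lo], "time_months"],
                             surv.loc[lo.index[lo], "event"],
                             surv.loc[lo.index[~lo], "event"])
            stat = float(np.sqrt(res.test_statistic))
            if stat > best[1] + 1e-12:
                best = (float(c), stat)
        return best

    def test_matches_exhaustive_per_split_logrank(self, rng):
        score = pd.Series(rng.normal(size=60),
                          index=[f"s{i}" for i in range(60)])
        surv = weibull_survival(score.to_numpy() * 0.5, rng)
        surv.index = score.index
        cut = max_sel_cutpoint(score, surv)
        b_cut, b_stat = self._brute(score, surv)
        assert cut.cutpoint == pytest.approx(b_cut)
        assert cut.statistic == pytest.approx(b_stat, rel=1e-9)

    def test_strong_separation_lands_between_groups(self, rng):
        """Short survivors score 1-5, long survivors score 10-15; the
        selected cutpoint falls in the score gap."""
        n_per = 30
        score = pd.Series(
            np.r_[rng.uniform(1.0, 5.0, n_per), rng.uniform(10.0, 15.0, n_per)],
            index=[f"s{i}" for i in range(2 * n_per)])
        times = np.r_[rng.uniform(1.0, 20.0, n_per),
                      rng.uniform(100.0, 200.0, n_per)]
        surv = _surv(times, np.ones(2 * n_per, int), index=score.index)
        cut = max_sel_cutpoint(score, surv, minprop=0.1)
        assert 5.0 < cut.cutpoint < 10.0

    def test_minprop_bound_respected(self, rng):
        score = pd.Series(rng.normal(size=100),
                          index=[f"s{i}" for i in range(100)])
        surv = weibull_survival(np.zeros(100), rng)
        surv.index = score.index
        cut = max_sel_cutpoint(score, surv, minprop=0.1)
        assert min((cut.labels == "low").sum(),
                   (cut.labels == "high").sum()) >= 10

    def test_invariant_to_monotone_score_transform(self, rng):
        score = pd.Series(rng.normal(size=50),
                          index=[f"s{i}" for i in range(50)])
        surv = weibull_survival(score.to_numpy(), rng)
        surv.index = score.index
        c1 = max_sel_cutpoint(score, surv)
        c2 = max_sel_cutpoint(np.exp(score) * 3, surv)
        assert c1.labels.equals(c2.labels)
        assert c1.statistic == pytest.approx(c2.statistic)

    def test_corrected_p_not_smaller_than_pointwise(self, rng):
        score = pd.Series(rng.normal(size=80),
                          index=[f"s{i}" for i in range(80)])
        surv = weibull_survival(np.zeros(80), rng)
        surv.index = score.index
        cut = max_sel_cutpoint(score, surv)
        # the selection-corrected p accounts for the maximisation, so it can
        # never undercut the pointwise Gaussian tail at the same statistic
        from scipy.stats import norm
        assert cut.p_corrected >= 2.0 * norm.sf(cut.statistic) - 1e-12
        assert 0 < cut.p_corrected <= 1

    def test_degenerate_score_rejected(self):
        score = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        surv = _surv([1, 2, 3], [1, 1, 1], index=list("abc"))
        with pytest.raises(ValueError, match="distinct"):
            max_sel_cutpoint(score, surv)


class TestLogrankKm:
    def test_identical_groups_null(self):
        surv = _surv([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=surv.index)
        chi2, p = logrank_test(groups, surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_life_table(self):
        # A events at 1,2,3; B events at 4,5,6:
        # O_A=3, E_A=0.5+0.4+0.25=1.15, V=0.25+0.24+0.1875=0.6775
        surv = _surv([1, 2, 3, 4, 5, 6], [1] * 6)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=surv.index)
        chi2, _ = logrank_test(groups, surv)
        assert chi2 == pytest.approx((3 - 1.15) ** 2 / 0.6775, rel=1e-9)

    def test_km_no_censoring_is_empirical_survivor(self):
        times = [2.0, 4.0, 6.0, 8.0]
        surv = _surv(times, [1] * 4)
        groups = pd.Series(["g"] * 4, index=surv.index)
        km = km_curves(groups, surv)["g"]
        for i, t in enumerate(times):
            assert km.loc[t, "survival"] == pytest.approx(1 - (i + 1) / 4)

    def test_single_group_rejected(self):
        surv = _surv([1, 2], [1, 1])
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test(pd.Series(["A", "A"], index=surv.index), surv)


class TestCoxModel:
    def test_planted_log_hr_recovered(self, rng):
        x = rng.normal(size=1000)
        surv = weibull_survival(0.7 * x, rng)
        cov = pd.DataFrame({"x": x}, index=surv.index)
        tab = cox_model(cov, surv)
        assert tab.loc["x", "log_hr"] == pytest.approx(0.7, abs=0.15)
        assert tab.loc["x", "ci_lower"] < tab.loc["x", "hazard_ratio"] \
            < tab.loc["x", "ci_upper"]

    def test_collinear_covariates_rejected(self, rng):
        x = rng.normal(size=100)
        surv = weibull_survival(np.zeros(100), rng)
        cov = pd.DataFrame({"x": x, "x_copy": x.copy()}, index=surv.index)
        with pytest.raises(CollinearityError):
            cox_model(cov, surv, multivariate=True)

    def test_null_ci_coverage(self, rng):
        """Wald CIs of a null covariate cover 0 in >= 93/100 replicates."""
        from rcdgp._cox import cox_newton_univariate
        n, reps = 400, 100
        surv = weibull_survival(np.zeros(n), rng)
        X = rng.normal(size=(reps, n))
        res = cox_newton_univariate(X, surv["time_months"].to_numpy(),
                                    surv["event"].to_numpy())
        cover = np.abs(res["log_hr"]) < 1.96 * res["se"]
        assert cover.sum() >= 93


class TestConcordanceAuc:
    def test_perfect_score_no_censoring(self):
        times = np.arange(1.0, 51.0)
        surv = _surv(times, [1] * 50)
        score = pd.Series(-times, index=surv.index)
        out = concordance_and_auc(score, surv, horizons=(25.0,))
        assert out["c_index"] == pytest.approx(1.0)

    def test_random_score_near_half(self, rng):
        n = 1500
        surv = weibull_survival(np.zeros(n), rng)
        score = pd.Series(rng.normal(size=n), index=surv.index)
        out = concordance_and_auc(score, surv, horizons=(24.0,))
        assert out["c_index"] == pytest.approx(0.5, abs=0.03)

    def test_no_censoring_auc_equals_unweighted(self, rng):
        n, h = 300, 20.0
        lp = rng.normal(size=n)
        t = 24 * (-np.log(rng.uniform(size=n)) / np.exp(lp)) ** (1 / 1.2)
        surv = _surv(t, [1] * n)
        score = pd.Series(lp, index=surv.index)
        out = concordance_and_auc(score, surv, horizons=(h,))
        cases = t <= h
        s = score.to_numpy()
        num = (s[cases][:, None] > s[~cases][None, :]).sum() \
            + 0.5 * (s[cases][:, None] == s[~cases][None, :]).sum()
        unweighted = num / (cases.sum() * (~cases).sum())
        assert out["auc"][h] == pytest.approx(unweighted, rel=1e-9)

    def test_horizon_beyond_followup_omitted(self, rng):
        surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])
        score = pd.Series([4.0, 3.0, 2.0, 1.0], index=surv.index)
        out = concordance_and_auc(score, surv, horizons=(2.5, 500.0))
        assert out["auc"][500.0] is None
        assert out["auc"][2.5] is not None


class TestMeta:
    def test_single_study_identity(self):
        m = meta_hr([0.5], [0.2])
        assert m.fixed_log_hr == pytest.approx(0.5)
        assert m.random_log_hr == pytest.approx(0.5)
        assert m.I2 == 0.0 and m.df == 0

    def test_two_identical_studies(self):
        m = meta_hr([0.4, 0.4], [0.1, 0.1])
        assert m.Q == pytest.approx(0.0, abs=1e-12)
        assert m.I2 == 0.0
        assert m.fixed_log_hr == pytest.approx(0.4)

    def test_hand_computed_two_study_pooling(self):
        # equal weights: fixed = (0.2+0.6)/2 = 0.4; fixed SE = 0.1/sqrt(2)
        m = meta_hr([0.2, 0.6], [0.1, 0.1])
        assert m.fixed_log_hr == pytest.approx(0.4)
        assert m.fixed_se == pytest.approx(0.1 / np.sqrt(2))
        # Q = 8 > df=1 -> tau2 > 0 and random-effects SE exceeds fixed
        assert m.Q == pytest.approx(8.0)
        assert m.random_se >= m.fixed_se

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(20):
            k = rng.integers(2, 6)
            m = meta_hr(rng.normal(size=k), rng.uniform(0.05, 0.5, size=k))
            assert m.random_se >= m.fixed_se - 1e-12
            assert 0.0 <= m.I2 <= 100.0

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            meta_hr([0.1], [0.0])
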