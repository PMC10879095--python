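"""Gene-pair indicators, the Cox screen, and the RCD.GP score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import CoxPHFitter

from rcdgp.pairs import (GenePairSignature, build_pair_matrix,
                         filter_portable_pairs, rcdgp_score, select_signature,
                         univariate_cox_screen)
from tests.conftest import weibull_survival


def pair_count_oracle(n):
    c = 0
    for i in range(n):
        for j in range(i + 1, n):
            c += 1
    return c


class TestPairMatrix:
    def test_indicator_branches(self):
        expr = pd.DataFrame({"s1": [5.0, 3.0], "s2": [2.0, 2.0]},
                            index=["ga", "gb"])
        pm = build_pair_matrix(expr, ["ga", "gb"])
        assert pm.values.loc[("ga", "gb"), "s1"] == 1     # Ex > Ey
        assert pm.values.loc[("ga", "gb"), "s2"] == 0     # tie -> 0

    def test_three_genes_three_pairs(self, toy_expr):
        pm = build_pair_matrix(toy_expr, ["g1", "g2", "g3"])
        assert pm.n_pairs == 3

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=2, max_value=40))
    def test_pair_count_matches_double_loop(self, n):
        rng = np.random.default_rng(n)
        expr = pd.DataFrame(rng.normal(size=(n, 3)),
                            index=[f"g{i:03d}" for i in range(n)])
        pm = build_pair_matrix(expr, list(expr.index))
        assert pm.n_pairs == pair_count_oracle(n)

    def test_canonical_orientation_and_antisymmetry(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 20)),
                            index=[f"g{i}" for i in range(10)])
        pm = build_pair_matrix(expr, list(expr.index))
        for gx, gy in pm.pairs:
            assert gx < gy
        # Score(xy) + Score(yx) == 1 unless tied (here values are continuous)
        sub = expr.loc[["g1", "g2"]]
        fwd = (sub.loc["g1"] > sub.loc["g2"]).astype(int)
        rev = (sub.loc["g2"] > sub.loc["g1"]).astype(int)
        assert ((fwd + rev) == 1).all()

    def test_missing_genes_dropped_and_recorded(self, toy_expr):
        pm = build_pair_matrix(toy_expr, ["g1", "g2", "nope"])
        assert pm.dropped_genes == ["nope"]
        assert pm.n_pairs == 1

    def test_portability_filter(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 30)),
                            index=["a", "b", "c", "d"])
        expr.loc["d"] = 100.0          # constant indicator vs everything
        pm = build_pair_matrix(expr, list(expr.index))
        presence = pd.DataFrame(
            {"v1": [True, True, True, True], "v2": [True, False, True, True]},
            index=["a", "b", "c", "d"])
        kept = filter_portable_pairs(pm, presence, min_fraction=1.0)
        assert all("b" not in p for p in kept.pairs)      # absent in v2
        assert all("d" not in p for p in kept.pairs)      # constant indicator
        ident = filter_portable_pairs(pm, presence, min_fraction=0.0,
                                      drop_constant=False)
        assert ident.n_pairs == pm.n_pairs


class TestCoxScreen:
    def test_matches_lifelines_on_informative_pairs(self, rng):
        expr = pd.DataFrame(rng.normal(size=(12, 100)),
                            index=[f"g{i:02d}" for i in range(12)])
        surv = weibull_survival(0.8 * (expr.loc["g00"] > expr.loc["g01"])
                                .to_numpy(), rng)
        surv.index = expr.columns
        pm = build_pair_matrix(expr, list(expr.index))
        scr = univariate_cox_screen(pm, surv)
        freq = pm.values.mean(axis=1)
        check = freq[(freq > 0.25) & (freq < 0.75)].index[:4]
        for pair in check:
            df = pd.DataFrame({"x": pm.values.loc[pair].astype(float),
                               "t": surv["time_months"], "e": surv["event"]})
            cph = CoxPHFitter().fit(df, "t", "e")
            assert scr.loc[pair, "log_hr"] == pytest.approx(
                cph.params_["x"], abs=1e-4)
            assert scr.loc[pair, "p_value"] == pytest.approx(
                cph.summary.loc["x", "p"], abs=1e-4)

    def test_constant_covariate_flagged_p_one(self, rng):
        expr = pd.DataFrame(rng.normal(size=(2, 50)), index=["a", "b"])
        expr.loc["b"] = expr.loc["a"] - 1.0       # a > b always
        surv = weibull_survival(np.zeros(50), rng)
        surv.index = expr.columns
        pm = build_pair_matrix(expr, ["a", "b"])
        scr = univariate_cox_screen(pm, surv)
        row = scr.iloc[0]
        assert not row["converged"] and row["p_value"] == 1.0

    def test_zero_events_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 20)), index=["a", "b", "c"])
        surv = weibull_survival(np.zeros(20), rng)
        surv.index = expr.columns
        surv["event"] = 0
        pm = build_pair_matrix(expr, list(expr.index))
        with pytest.raises(ValueError, match="events"):
            univariate_cox_screen(pm, surv)

    def test_null_type_i_error_rate(self, rng):
        """Empirical pass rate of a null binary covariate at alpha=0.05."""
        n, reps = 1000, 400
        surv = weibull_survival(np.zeros(n), rng)
        X = (rng.uniform(size=(reps, n)) > 0.5).astype(float)
        from rcdgp._cox import cox_newton_univariate
        res = cox_newton_univariate(X, surv["time_months"].to_numpy(),
                                    surv["event"].to_numpy())
        rate = float((res["p"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_power_at_planted_log_hr_one(self, rng):
        """Planted binary effect with log HR 1, n=300: power >= 0.9."""
        hits = 0
        reps = 60
        from rcdgp._cox import cox_newton_univariate
        for _ in range(reps):
            x = (rng.uniform(size=300) > 0.5).astype(float)
            surv = weibull_survival(1.0 * x, rng, censor_quantile=0.8)
            res = cox_newton_univariate(x[None, :],
                                        surv["time_months"].to_numpy(),
                                        surv["event"].to_numpy())
            hits += res["p"][0] < 0.05
        assert hits / reps >= 0.9


class TestSignature:
    def _screen(self, pvals, cohort):
        idx = pd.MultiIndex.from_tuples(
            [(f"g{i}", f"h{i}") for i in range(len(pvals))],
            names=["gene_x", "gene_y"])
        return pd.DataFrame({
            "hazard_ratio": 2.0, "log_hr": 0.7, "log_hr_se": 0.2,
            "p_value": pvals, "converged": True, "cohort": cohort}, index=idx)

    def test_dual_cohort_rule(self):
        a = self._screen([0.01, 0.01, 0.2], "A")
        b = self._screen([0.01, 0.3, 0.01], "B")
        sig = select_signature(a, b)
        assert sig.pairs == [("g0", "h0")]
        assert sig.provenance["pass_both"] == 1

    def test_empty_selection_reports_funnel(self):
        a = self._screen([0.5, 0.6], "A")
        b = self._screen([0.5, 0.6], "B")
        with pytest.raises(ValueError, match="funnel"):
            select_signature(a, b)

    def test_score_summation_and_empty(self, toy_expr):
        pm = build_pair_matrix(toy_expr, list(toy_expr.index))
        empty = GenePairSignature(pairs=[])
        assert (rcdgp_score(pm, empty) == 0).all()
        three = GenePairSignature(pairs=pm.pairs[:3])
        expected = pm.values.iloc[:3].sum(axis=0)
        assert rcdgp_score(pm, three).equals(expected.rename("rcdgp_score"))

    def test_score_brute_force_and_integer_range(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 25)),
                            index=[f"g{i}" for i in range(8)])
        pm = build_pair_matrix(expr, list(expr.index))
        sig = GenePairSignature(pairs=pm.pairs[::3])
        got = rcdgp_score(expr, sig)
        brute = np.zeros(25, dtype=int)
        for gx, gy in sig.pairs:
            brute += (expr.loc[gx].to_numpy() > expr.loc[gy].to_numpy())
        np.testing.assert_array_equal(got.to_numpy(), brute)
        assert got.between(0, len(sig)).all()

    def test_score_invariant_to_per_sample_monotone_transform(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 25)),
                            index=[f"g{i}" for i in range(8)])
        sig = GenePairSignature(
            pairs=build_pair_matrix(expr, list(expr.index)).pairs[:10])
        base = rcdgp_score(expr, sig)
        warped = expr.copy()
        for j, c in enumerate(expr.columns):    # different map per sample
            warped[c] = np.exp(expr[c] * (1 + 0.1 * j)) + j
        assert rcdgp_score(warped, sig).equals(base)

    def test_missing_signature_gene_raises(self, toy_expr):
        sig = GenePairSignature(pairs=[("g1", "zzz")])
        with pytest.raises(KeyError, match="zzz"):
            rcdgp_score(toy_expr, sig)

    def test_signature_roundtrip(self, tmp_path, toy_expr):
        pm = build_pair_matrix(toy_expr, list(toy_expr.index))
        sig = GenePairSignature(pairs=pm.pairs[:4])
        path = tmp_path / "sig.tsv"
        sig.to_tsv(path)
        back = GenePairSignature.from_tsv(path)
        assert back.pairs == sig.pairs
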