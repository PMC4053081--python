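import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_survival_dataset
from oracles import bh_naive, breslow_loglik_naive, cox_beta_1d_oracle
from survnet.cox import CoxEngine, bh_adjust, chi2_sf, cox_fit, univariate_cox, wald_p
from survnet.expression_io import SurvivalData


class TestCoxFit:
    def test_binary_covariate_matches_1d_oracle(self):
        # interleaved groups: both arms keep failing throughout follow-up,
        # so the partial likelihood has an interior maximum
        x = np.array([1.0, 0, 1, 0, 1, 0])
        surv = SurvivalData(
            tuple(f"S{i}" for i in range(6)),
            np.arange(1.0, 7.0),
            np.ones(6, dtype=int),
        )
        fit = cox_fit(x[:, None], surv)
        oracle = cox_beta_1d_oracle(x, surv.time, surv.event)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("trial", range(10))
    def test_random_small_datasets_match_1d_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        X, surv = random_survival_dataset(rng, n=12, p=1, censor_frac=0.2)
        fit = cox_fit(X, surv)
        if not fit.converged:
            pytest.skip("degenerate draw")
        oracle = cox_beta_1d_oracle(X[:, 0], surv.time, surv.event)
        assert fit.beta[0] == pytest.approx(oracle, abs=1e-4)

    def test_loglik_at_zero_closed_form(self):
        rng = np.random.default_rng(5)
        X, surv = random_survival_dataset(rng, n=10, p=1, censor_frac=0.3)
        engine = CoxEngine(surv)
        ll0 = engine.loglik(engine._prepare(X), np.zeros(1))
        # with no ties, each event contributes -log(risk-set size) at beta=0
        expected = -sum(
            np.log((surv.time >= t).sum())
            for t, e in zip(surv.time, surv.event)
            if e == 1
        )
        assert ll0 == pytest.approx(expected, abs=1e-12)

    def test_fitted_loglik_never_below_null(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            X, surv = random_survival_dataset(rng, n=15, p=2, censor_frac=0.2)
            engine = CoxEngine(surv)
            fit = engine.fit(X)
            ll0 = engine.loglik(engine._prepare(X), np.zeros(2))
            assert fit.log_partial_likelihood >= ll0 - 1e-10

    def test_loglik_matches_naive_formula(self):
        rng = np.random.default_rng(21)
        X, surv = random_survival_dataset(rng, n=9, p=2, censor_frac=0.2)
        engine = CoxEngine(surv)
        beta = np.array([0.4, -0.7])
        assert engine.loglik(engine._prepare(X), beta) == pytest.approx(
            breslow_loglik_naive(beta, X, surv.time, surv.event), abs=1e-10
        )

    def test_constant_covariate_flagged_not_raised(self):
        surv = SurvivalData(
            tuple(f"S{i}" for i in range(6)),
            np.arange(1.0, 7.0),
            np.ones(6, dtype=int),
        )
        fit = cox_fit(np.ones((6, 1)), surv)
        assert not fit.converged
        assert fit.p_value == 1.0

    def test_collinear_columns_flagged(self):
        rng = np.random.default_rng(3)
        X, surv = random_survival_dataset(rng, n=20, p=1)
        XX = np.hstack([X, 2 * X])
        fit = cox_fit(XX, surv)
        assert not fit.converged

    def test_no_events_errors(self):
        surv_ok = SurvivalData(("a", "b"), np.array([1.0, 2.0]), np.array([0, 1]))
        assert CoxEngine(surv_ok) is not None
        with pytest.raises(ValueError, match="no events"):
            CoxEngine(
                SurvivalData(("a", "b"), np.array([1.0, 2.0]), np.array([0, 0]))
            )

    def test_invariant_under_sample_relabeling(self):
        rng = np.random.default_rng(8)
        X, surv = random_survival_dataset(rng, n=25, p=3, censor_frac=0.3)
        fit1 = cox_fit(X, surv)
        perm = rng.permutation(25)
        surv2 = SurvivalData(
            tuple(surv.sample_ids[i] for i in perm), surv.time[perm], surv.event[perm]
        )
        fit2 = cox_fit(X[perm], surv2)
        assert np.allclose(fit1.beta, fit2.beta, atol=1e-8)
        assert fit1.p_value == pytest.approx(fit2.p_value, abs=1e-8)

    def test_matches_lifelines_multivariate(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(42)
        X, surv = random_survival_dataset(rng, n=60, p=3, censor_frac=0.3)
        fit = cox_fit(X, surv)
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        df["T"], df["E"] = surv.time, surv.event
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-6)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-6)

    def test_efron_ties_match_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(9)
        n = 40
        X = rng.standard_normal((n, 2))
        time = rng.integers(1, 8, size=n).astype(float)  # heavy ties
        event = (rng.uniform(size=n) > 0.25).astype(int)
        event[:2] = 1
        surv = SurvivalData(tuple(f"S{i}" for i in range(n)), time, event)
        fit = cox_fit(X, surv, ties="efron")
        df = pd.DataFrame(X, columns=["x0", "x1"])
        df["T"], df["E"] = time, event
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")  # lifelines uses Efron
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-5)

    def test_warm_start_reaches_same_optimum(self):
        rng = np.random.default_rng(17)
        X, surv = random_survival_dataset(rng, n=30, p=2, censor_frac=0.2)
        cold = cox_fit(X, surv)
        warm = cox_fit(X, surv, beta0=np.array([1.5, -1.5]))
        assert np.allclose(cold.beta, warm.beta, atol=1e-7)


class TestWaldP:
    def test_chi2_quantile(self):
        assert chi2_sf(3.841459, 1) == pytest.approx(0.05, abs=1e-6)

    def test_zero_stat_gives_one(self):
        assert chi2_sf(0.0, 3) == 1.0

    def test_monotone_in_stat(self):
        stats = np.linspace(0, 20, 50)
        ps = [chi2_sf(s, 2) for s in stats]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_wald_p_requires_convergence(self):
        surv = SurvivalData(
            tuple(f"S{i}" for i in range(6)),
            np.arange(1.0, 7.0),
            np.ones(6, dtype=int),
        )
        good = cox_fit(np.array([[0.1], [2.0], [0.3], [1.2], [0.7], [1.9]]), surv)
        assert wald_p(good) == pytest.approx(good.p_value)
        bad = cox_fit(np.ones((6, 1)), surv)
        with pytest.raises(ValueError):
            wald_p(bad)


class TestUnivariateCox:
    def test_duplicate_gene_rows_identical(self):
        rng = np.random.default_rng(2)
        X, surv = random_survival_dataset(rng, n=30, p=1, censor_frac=0.2)
        m = pd.DataFrame(
            np.vstack([X[:, 0], X[:, 0], rng.standard_normal(30)]),
            index=["A", "A2", "B"],
            columns=surv.sample_ids,
        )
        out = univariate_cox(m, surv)
        assert out.loc["A", "beta"] == pytest.approx(out.loc["A2", "beta"])
        assert out.loc["A", "p"] == pytest.approx(out.loc["A2", "p"])

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X, surv = random_survival_dataset(rng, n=25, p=1, censor_frac=0.2)
        m = pd.DataFrame(X.T, index=["A"], columns=surv.sample_ids)
        out1 = univariate_cox(m, surv)
        perm = rng.permutation(25)
        surv2 = SurvivalData(
            tuple(surv.sample_ids[i] for i in perm), surv.time[perm], surv.event[perm]
        )
        out2 = univariate_cox(m, surv2)  # columns re-matched by sample id
        assert out1.loc["A", "p"] == pytest.approx(out2.loc["A", "p"], abs=1e-10)

    def test_empty_matrix_errors(self):
        surv = SurvivalData(("a", "b"), np.array([1.0, 2.0]), np.array([1, 1]))
        with pytest.raises(ValueError):
            univariate_cox(pd.DataFrame(columns=["a", "b"]), surv)


class TestBHAdjust:
    def test_textbook_example(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_all_ones(self):
        assert bh_adjust([0.3]).tolist() == [0.3]
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_naive_stepup(self, trial):
        rng = np.random.default_rng(trial)
        p = rng.uniform(size=int(rng.integers(1, 40)))
        assert np.allclose(bh_adjust(p), bh_naive(p), atol=1e-12)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(77)
        p = rng.uniform(size=50)
        ours = bh_adjust(p)
        theirs = sm.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_properties(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        # monotone: larger p never gets a smaller adjusted value
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
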