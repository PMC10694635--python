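import numpy as np
import pytest
from scipy.special import expit

from subvaltest.data_model import DataError, SurvivalTrialData, UncensoredTrialData
from subvaltest.nuisance import (CensoringModel, StepCurves,
                                 censoring_augmentation, conditional_rmst,
                                 fit_censoring_model, fit_outcome_models,
                                 fit_propensity, fit_survival_models,
                                 SurvivalForestNuisanceLearner)
from subvaltest.simulation import gen_aft, gen_model1, model1_tau

from _oracles import martingale_integral, residual_rmst
from conftest import make_survival_fit


class TestPropensity:
    def test_known_mode_constant(self, toy_table, rng):
        from subvaltest.data_model import validate_uncensored
        data = validate_uncensored(toy_table, known_pi=0.5)
        pi = fit_propensity(data, "known")
        np.testing.assert_allclose(pi(rng.normal(size=(7, 2))), 0.5)

    def test_logistic_recovers_marginal_rate(self, rng):
        n = 2000
        X = rng.normal(size=(n, 3))
        A = (rng.random(n) < 0.5).astype(int)
        data = UncensoredTrialData(X, A, rng.normal(size=n))
        pi = fit_propensity(data, "logistic")
        se = np.sqrt(0.25 / n)
        assert abs(pi(X).mean() - 0.5) < 3 * se

    def test_logistic_recovers_coefficients(self, rng):
        # A ~ Bernoulli(expit(-0.3 + 0.2 X1 + 0.6 X5)), five covariates
        n = 5000
        X = np.column_stack([rng.normal(size=(n, 3)),
                             rng.integers(0, 2, (n, 2))])
        eta = -0.3 + 0.2 * X[:, 0] + 0.6 * X[:, 4]
        A = (rng.random(n) < expit(eta)).astype(int)
        data = UncensoredTrialData(X, A, rng.normal(size=n))
        fit_propensity(data, "logistic")  # smoke: clipped callable
        import statsmodels.api as sm
        res = sm.Logit(A, sm.add_constant(X)).fit(disp=0)
        truth = np.array([-0.3, 0.2, 0.0, 0.0, 0.0, 0.6])
        assert np.all(np.abs(res.params - truth) < 3 * res.bse)

    def test_single_arm_history_fails(self, rng):
        data = UncensoredTrialData(rng.normal(size=(20, 2)),
                                   np.r_[np.zeros(19, int), 1],
                                   rng.normal(size=20))
        data.A[:] = 0  # force degenerate after construction
        with pytest.raises(DataError, match="degenerate"):
            fit_propensity(data, "logistic")


class TestOutcomeForests:
    def test_recovers_constant_treatment_effect(self, rng):
        n = 4000
        X = rng.normal(size=(n, 3))
        A = rng.integers(0, 2, n)
        Y = 1.0 + X[:, 0] + 2.0 * A  # noiseless
        data = UncensoredTrialData(X, A, Y)
        _, tau_hat = fit_outcome_models(data, n_estimators=100, random_state=0)
        fresh = rng.normal(size=(500, 3))
        assert np.mean(np.abs(tau_hat(fresh) - 2.0)) < 0.25

    def test_constant_outcome(self, rng):
        X = rng.normal(size=(200, 2))
        A = rng.integers(0, 2, 200)
        data = UncensoredTrialData(X, A, np.full(200, 5.0))
        c0_hat, tau_hat = fit_outcome_models(data, n_estimators=30, random_state=0)
        np.testing.assert_allclose(c0_hat(X), 5.0)
        np.testing.assert_allclose(tau_hat(X), 0.0, atol=1e-12)

    def test_cate_sign_agreement_above_chance(self, rng):
        # tau = 0 on ~58% of the population where any unbiased estimator's
        # sign is a coin flip, so perfect agreement is unattainable; require
        # clearly-above-chance agreement on the signal region
        data = gen_model1(2000, 0.5, 1, "bernoulli", rng)
        _, tau_hat = fit_outcome_models(data, n_estimators=100, random_state=0)
        fresh = gen_model1(4000, 0.5, 1, "bernoulli", rng)
        agree = np.mean((tau_hat(fresh.X) > 0) == (model1_tau(fresh.X, 0.5) > 0))
        assert agree >= 0.55

    def test_too_few_in_arm_names_arm(self, rng):
        X = rng.normal(size=(30, 2))
        A = np.r_[np.zeros(27, int), np.ones(3, int)]
        data = UncensoredTrialData(X, A, rng.normal(size=30))
        with pytest.raises(DataError, match="arm 1"):
            fit_outcome_models(data, n_estimators=10)


class TestSurvivalCurvesAndRmst:
    def test_full_survival_gives_rmst_L(self):
        sc = StepCurves(np.array([1.0, 2.0]), np.ones((3, 2)))
        np.testing.assert_allclose(sc.rmst(10.0), 10.0)
        np.testing.assert_allclose(sc.conditional_rmst_at(np.float64(0.0), 10.0), 10.0)

    def test_exponential_rmst_closed_form(self):
        lam, L = 0.3, 5.0
        grid = np.linspace(0, L, 4001)[1:]
        sc = StepCurves(grid, np.exp(-lam * grid)[None, :])
        expected = (1 - np.exp(-lam * L)) / lam
        assert abs(sc.rmst(L)[0] - expected) < 2e-3

    def test_aft_positive_effect_detected(self, rng):
        data = gen_aft(800, 1.25, "normal", "b", "bernoulli", rng)
        _, _, tau_hat = fit_survival_models(data, data.L, n_estimators=50,
                                            min_samples_leaf=30, random_state=0)
        assert tau_hat(gen_aft(400, 1.25, "normal", "b", "bernoulli", rng).X).mean() > 0

    def test_arm_without_events_fails(self, rng):
        n = 60
        X = rng.normal(size=(n, 2))
        A = rng.integers(0, 2, n)
        A[:2] = [0, 1]
        U = rng.exponential(5, n)
        Delta = np.where(A == 1, 0, 1)
        data = SurvivalTrialData(X, A, U, Delta, L=float(np.quantile(U, 0.5)))
        with pytest.raises(DataError, match="zero observed events"):
            fit_survival_models(data, data.L, n_estimators=10)


class TestConditionalRmst:
    def test_at_truncation_time(self):
        grid = np.array([1.0, 2.0, 3.0])
        surv = np.array([0.8, 0.5, 0.2])
        assert conditional_rmst(grid, surv, 3.0, 3.0) == pytest.approx(3.0)

    def test_point_mass(self):
        # S drops from 1 to 0 at t=5: conditional mean is the atom
        assert conditional_rmst(np.array([5.0]), np.array([0.0]), 0.0, 10.0) \
            == pytest.approx(5.0)

    def test_exponential_closed_form(self):
        lam, L = 0.4, 6.0
        grid = np.linspace(0, L, 6001)[1:]
        surv = np.exp(-lam * grid)
        for r in (0.0, 1.5, 4.0):
            expected = r + (1 - np.exp(-lam * (L - r))) / lam
            assert abs(conditional_rmst(grid, surv, r, L) - expected) < 5e-3

    def test_monotone_and_bounded_matches_bruteforce(self, rng):
        for _ in range(20):
            k = rng.integers(2, 8)
            times = np.sort(rng.uniform(0.1, 9.0, k))
            surv = np.sort(rng.uniform(0.05, 1.0, k))[::-1]
            L = 10.0
            rs = np.linspace(0, L, 25)
            vals = [conditional_rmst(times, surv, r, L) for r in rs]
            assert np.all(np.diff(vals) >= -1e-9)
            for r, v in zip(rs, vals):
                assert r - 1e-9 <= v <= L + 1e-9
                assert v == pytest.approx(residual_rmst(times, surv, r, L), abs=1e-9)

    def test_r_beyond_L_rejected(self):
        with pytest.raises(ValueError):
            conditional_rmst(np.array([1.0]), np.array([0.5]), 4.0, 3.0)


class TestCensoringModel:
    def test_no_censoring_degenerates_with_warning(self, rng):
        n = 60
        data = SurvivalTrialData(rng.normal(size=(n, 2)),
                                 rng.integers(0, 2, n) | (np.arange(n) < 2),
                                 rng.exponential(5, n), np.ones(n, int),
                                 L=1.0)
        with pytest.warns(UserWarning, match="no censoring"):
            cm = fit_censoring_model(data)
        assert cm.times.size == 0
        np.testing.assert_allclose(cm.survival(np.float64(3.0), data.X, data.A), 1.0)

    def test_independent_exponential_censoring_recovered(self, rng):
        n, rho = 4000, 1 / 20.0
        X = rng.normal(size=(n, 2))
        A = rng.integers(0, 2, n)
        T = rng.exponential(30.0, n)
        C = rng.exponential(1 / rho, n)
        U, Delta = np.minimum(T, C), (T <= C).astype(int)
        data = SurvivalTrialData(X, A, U, Delta, L=float(np.quantile(U, 0.8)))
        cm = fit_censoring_model(data)
        for t in np.quantile(U, np.linspace(0.1, 0.9, 9)):
            khat = float(np.mean(cm.survival(np.float64(t), X, A)))
            assert abs(khat - np.exp(-rho * t)) < 0.05

    def test_treatment_log_hazard_ratio_recovered(self, rng):
        # censoring hazard depends on X1 and A; cross-check against an
        # independent Cox implementation and its standard errors
        import lifelines
        import pandas as pd
        n = 5000
        X = np.column_stack([rng.normal(size=(n, 3)),
                             rng.integers(0, 2, (n, 2))])
        A = rng.integers(0, 2, n)
        rate = np.exp(-3.5 + 0.1 * X[:, 0] + 0.2 * A)
        C = rng.exponential(1 / rate)
        T = rng.exponential(60.0, n)
        U, Delta = np.minimum(T, C), (T <= C).astype(int)
        data = SurvivalTrialData(X, A, U, Delta, L=float(np.quantile(U, 0.8)))
        cm = fit_censoring_model(data)
        df = pd.DataFrame(np.column_stack([X, A, U, 1 - Delta]),
                          columns=[*(f"x{i}" for i in range(5)), "a", "t", "e"])
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        a_se = cph.summary.loc["a", "se(coef)"]
        assert abs(cm.coef[-1] - 0.2) < 3 * a_se
        assert abs(cm.coef[-1] - cph.params_["a"]) < 1e-3


class TestCensoringAugmentation:
    def test_null_when_no_hazard_and_event_observed(self, rng):
        fit = make_survival_fit(
            np.array([2.0]), lambda X, a: np.full((X.shape[0], 1), 0.7),
            CensoringModel(np.empty(0), np.empty(0)), L=5.0)
        assert censoring_augmentation((rng.normal(size=2), 1, 3.0, 1), fit) == 0.0

    def test_single_step_hand_value(self):
        # one hazard step of size h at t0, flat survival so m === L
        h, t0, L, ul = 0.3, 1.0, 6.0, 4.0
        cm = CensoringModel(np.array([t0]), np.array([h]))
        fit = make_survival_fit(
            np.array([L + 1.0]), lambda X, a: np.ones((X.shape[0], 1)), cm, L)
        kc = np.exp(-h)
        expected = L / kc - h * L / kc
        got = censoring_augmentation((np.zeros(2), 1, ul, 0), fit)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_mean_zero_under_true_censoring_law(self):
        # known exponential censoring: the augmentation is a mean-zero
        # martingale integral, so its sample average vanishes
        from subvaltest.scores import _augmentation_vector
        from subvaltest.simulation import OracleAFTLearner, SimDesign
        d = SimDesign("aft_model1", c=0.75, n=10_000, censoring="b")
        data = d.sample(np.random.default_rng(42))
        fit = OracleAFTLearner(d, L=data.L, grid_size=800).fit(None)
        aug, _, _ = _augmentation_vector(data, fit)
        se = aug.std(ddof=1) / np.sqrt(len(aug))
        assert abs(aug.mean()) < 3 * se

    def test_two_term_form_equals_direct_martingale_sum(self, small_survival_data):
        # the implemented two-term rewrite must match the direct Stieltjes
        # evaluation of int dMc/Kc * m for every subject
        data = small_survival_data
        learner = SurvivalForestNuisanceLearner(n_estimators=20,
                                                min_samples_leaf=10,
                                                min_per_arm=2)
        fit = learner.fit(data, np.random.default_rng(0))
        cm = fit.cens
        for i in range(data.n):
            x, a = data.X[i], int(data.A[i])
            lp = float(cm.linpred(x[None, :], [a])[0])
            dlam = cm.base_dH * np.exp(lp)
            kc_at = lambda t: max(fit.kc_hat(t, x, a), 0.01)
            m_at = lambda t: fit.m_hat(min(t, data.L), x, a)
            direct = martingale_integral(data.UL[i], data.DeltaL[i],
                                         cm.times, dlam, kc_at, m_at)
            implemented = censoring_augmentation((x, a, data.UL[i],
                                                  data.DeltaL[i]), fit)
            assert implemented == pytest.approx(direct, abs=1e-10)
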