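"""Estimator correctness: recovery, oracle equivalences, Wald inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import log_ndtr
from scipy.stats import norm

from mltobit import (
    CensoringSpec,
    DesignConfig,
    MultilevelRegression,
    MultilevelTobit,
    PopulationParams,
    TwoLevelDataset,
    apply_floor,
    fit_naive_ml,
    fit_tobit,
    generate_two_level,
    loglik_tobit,
    robust_se,
    wald_infer,
)
from mltobit.estimators import (
    InsufficientClustersError,
    SingularDesignError,
)

from conftest import make_singleton_dataset


class TestNaiveML:
    def test_noise_free_data_recovered_exactly(self):
        rng = np.random.default_rng(1)
        G, m = 20, 5
        cid = np.repeat(np.arange(G), m)
        x1 = rng.standard_normal(G * m)
        x2 = rng.standard_normal(G)[cid]
        y = 1.0 + 0.75 * x1 + 0.5 * x2
        frame = pd.DataFrame(
            {"cluster_id": cid, "y_obs": y, "censored_low": False,
             "censored_high": False, "x1": x1, "x2": x2}
        )
        fit = fit_naive_ml(TwoLevelDataset(frame=frame))
        assert fit.estimates["intercept"] == pytest.approx(1.0, abs=1e-6)
        assert fit.estimates["x1"] == pytest.approx(0.75, abs=1e-6)
        assert fit.estimates["x2"] == pytest.approx(0.5, abs=1e-6)
        assert fit.estimates["var_within"] < 1e-8
        assert fit.estimates["var_between"] < 1e-8

    def test_parameter_recovery_large_sample(self):
        """One 500x10 draw: estimates within 3 MC SEs of the generating values."""
        data = generate_two_level(DesignConfig(n_clusters=500, cluster_size=10, seed=11))
        fit = fit_naive_ml(data)
        truth = {"intercept": 1.0, "x1": 0.75, "x2": 0.5,
                 "var_between": 0.5, "var_within": 1.0}
        for name, tv in truth.items():
            se = fit.std_errors[name]
            assert abs(fit.estimates[name] - tv) < 3 * se, name

    def test_matches_statsmodels_mixedlm(self):
        """Independent ML cross-check on an uncensored fixture."""
        statsmodels = pytest.importorskip("statsmodels.api")
        data = generate_two_level(DesignConfig(n_clusters=50, cluster_size=5, seed=3))
        fit = fit_naive_ml(data)
        md = statsmodels.MixedLM(
            data.y_obs,
            data.design_matrix(),
            groups=data.frame["cluster_id"].to_numpy(),
        )
        sm_fit = md.fit(reml=False)
        np.testing.assert_allclose(
            fit.fixed_effects.to_numpy(), sm_fit.fe_params, atol=1e-5
        )
        assert fit.estimates["var_between"] == pytest.approx(
            float(np.asarray(sm_fit.cov_re)[0, 0]), abs=1e-4
        )
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-5)

    def test_identical_cluster_means_give_ols(self):
        """When every cluster's residual mean coincides, phi -> 0 and GLS = OLS."""
        rng = np.random.default_rng(8)
        G = 40
        cid = np.repeat(np.arange(G), 2)
        x1 = rng.standard_normal(2 * G)
        x2 = rng.standard_normal(G)[cid]
        delta = rng.uniform(0.5, 1.5, G)
        e = np.stack([delta, -delta], axis=1).ravel()  # cluster means exactly 0
        y = 1.0 + 0.75 * x1 + 0.5 * x2 + e
        frame = pd.DataFrame(
            {"cluster_id": cid, "y_obs": y, "censored_low": False,
             "censored_high": False, "x1": x1, "x2": x2}
        )
        fit = fit_naive_ml(TwoLevelDataset(frame=frame))
        D = np.column_stack([np.ones(len(y)), x1, x2])
        ols = np.linalg.lstsq(D, y, rcond=None)[0]
        # phi is pushed toward its boundary only if the residual cluster means
        # are less dispersed than sampling noise predicts; with this design the
        # estimate is tiny and GLS shrinks to OLS.
        np.testing.assert_allclose(fit.fixed_effects.to_numpy(), ols, atol=1e-4)

    def test_requires_two_clusters(self):
        frame = pd.DataFrame(
            {"cluster_id": [0, 0, 0], "y_obs": [1.0, 2.0, 3.0],
             "censored_low": False, "censored_high": False,
             "x1": [0.1, 0.2, 0.3], "x2": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(InsufficientClustersError):
            fit_naive_ml(TwoLevelDataset(frame=frame))

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(2)
        cid = np.repeat(np.arange(5), 4)
        x1 = rng.standard_normal(20)
        frame = pd.DataFrame(
            {"cluster_id": cid, "y_obs": rng.standard_normal(20),
             "censored_low": False, "censored_high": False,
             "x1": x1, "x2": 2.0 * x1}
        )
        with pytest.raises(SingularDesignError):
            fit_naive_ml(TwoLevelDataset(frame=frame))


class TestRobustSE:
    def test_estimates_pass_through_bitwise(self, medium_floored_dataset):
        naive = fit_naive_ml(medium_floored_dataset)
        rob = robust_se(naive, medium_floored_dataset)
        assert rob.method == "robust"
        assert (rob.estimates == naive.estimates).all()

    def test_agrees_with_model_se_when_correctly_specified(self):
        data = generate_two_level(DesignConfig(n_clusters=500, cluster_size=10, seed=21))
        naive = fit_naive_ml(data)
        rob = robust_se(naive, data)
        for name in ("x1", "x2"):
            ratio = rob.std_errors[name] / naive.std_errors[name]
            assert abs(ratio - 1.0) < 0.10, name

    def test_singleton_clusters_equal_hc0_oracle(self):
        """With clusters of size 1 the cluster sandwich is the HC0 sandwich of
        the single-level normal ML fit (computed here from scratch)."""
        data = make_singleton_dataset()
        naive = fit_naive_ml(data)
        rob = robust_se(naive, data)
        n = data.n_obs
        D = data.design_matrix()
        beta = naive.fixed_effects.to_numpy()
        v = naive.estimates["var_within"] + naive.estimates["var_between"]
        r = data.y_obs - D @ beta
        # parameters (beta, v): per-observation scores and observed information
        S = np.column_stack([D * (r / v)[:, None], -0.5 / v + 0.5 * r**2 / v**2])
        p = D.shape[1]
        A = np.zeros((p + 1, p + 1))
        A[:p, :p] = D.T @ D / v
        A[:p, p] = A[p, :p] = D.T @ (r / v**2)
        A[p, p] = -0.5 * n / v**2 + np.sum(r**2) / v**3
        Ainv = np.linalg.inv(A)
        V = Ainv @ (S.T @ S) @ Ainv * (n / (n - 1.0))
        oracle_se = np.sqrt(np.diag(V))
        got = rob.std_errors[["intercept", "x1", "x2", "var_within"]].to_numpy()
        np.testing.assert_allclose(got, oracle_se, atol=1e-10, rtol=1e-8)
        assert np.isnan(rob.std_errors["var_between"])

    def test_requires_naive_fit(self, medium_floored_dataset):
        naive = fit_naive_ml(medium_floored_dataset)
        rob = robust_se(naive, medium_floored_dataset)
        with pytest.raises(ValueError):
            robust_se(rob, medium_floored_dataset)


def _single_level_tobit_oracle(y, X, lower, cens):
    """Independent single-level Tobit ML via the closed-form censored normal
    log-likelihood (no random intercept)."""

    def nll(theta):
        beta, log_s2 = theta[:-1], theta[-1]
        s = np.sqrt(np.exp(log_s2))
        mu = X @ beta
        ll = np.where(
            cens,
            log_ndtr((lower - mu) / s),
            norm.logpdf(y, mu, s),
        )
        return -ll.sum()

    beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
    x0 = np.concatenate([beta0, [np.log(np.var(y))]])
    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"gtol": 1e-9, "maxiter": 500})
    return res.x[:-1], float(np.exp(res.x[-1]))


class TestTobit:
    def test_reduces_to_naive_without_censoring(self, small_dataset):
        naive = fit_naive_ml(small_dataset)
        tob = fit_tobit(small_dataset, CensoringSpec())
        np.testing.assert_allclose(
            tob.fixed_effects.to_numpy(),
            naive.fixed_effects.to_numpy(),
            atol=1e-5,
        )
        assert tob.estimates["var_within"] == pytest.approx(
            naive.estimates["var_within"], abs=1e-4
        )

    def test_matches_single_level_tobit_oracle(self):
        """Singleton clusters: the multilevel Tobit collapses to a single-level
        Tobit on total variance; slopes must match an independent fit."""
        rng = np.random.default_rng(17)
        n = 400
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y_star = 0.5 + 0.8 * x1 - 0.3 * x2 + rng.standard_normal(n)
        lower = -0.5
        cens = y_star <= lower
        y = np.where(cens, lower, y_star)
        frame = pd.DataFrame(
            {"cluster_id": np.arange(n), "y_obs": y, "censored_low": cens,
             "censored_high": False, "x1": x1, "x2": x2}
        )
        data = TwoLevelDataset(frame=frame, spec=CensoringSpec(lower=lower))
        fit = fit_tobit(data)
        D = data.design_matrix()
        beta_o, s2_o = _single_level_tobit_oracle(y, D, lower, cens)
        np.testing.assert_allclose(fit.fixed_effects.to_numpy(), beta_o, atol=1e-3)
        # multilevel total variance (phi + sigma2) vs single-level sigma2
        total = fit.estimates["var_between"] + fit.estimates["var_within"]
        assert total == pytest.approx(s2_o, abs=2e-3)

    def test_loglik_at_optimum_beats_naive_start(self, medium_floored_dataset):
        data = medium_floored_dataset
        naive = fit_naive_ml(data)
        tob = fit_tobit(data)
        start = PopulationParams(
            naive.estimates["intercept"],
            naive.estimates["x1"],
            naive.estimates["x2"],
            max(naive.estimates["var_between"], 1e-6),
            naive.estimates["var_within"],
        )
        assert tob.loglik >= loglik_tobit(data, start) - 1e-8

    def test_all_censored_raises(self):
        frame = pd.DataFrame(
            {"cluster_id": [0, 0, 1, 1], "y_obs": [0.0] * 4,
             "censored_low": [True] * 4, "censored_high": [False] * 4,
             "x1": [0.1, 0.2, 0.3, 0.4], "x2": [1.0, 1.0, -1.0, -1.0]}
        )
        data = TwoLevelDataset(frame=frame, spec=CensoringSpec(lower=0.0))
        from mltobit.estimators import DegenerateDataError
        with pytest.raises(DegenerateDataError):
            fit_tobit(data)


class TestSklearnInterface:
    def test_get_set_params_roundtrip(self):
        est = MultilevelTobit(lower=-1.0, n_nodes=15)
        params = est.get_params()
        assert params["lower"] == -1.0 and params["n_nodes"] == 15
        est.set_params(n_nodes=31)
        assert est.n_nodes == 31

    def test_fit_predict_shapes(self, floored_dataset):
        X = floored_dataset.frame[["x1", "x2"]].to_numpy()
        y = floored_dataset.y_obs
        groups = floored_dataset.frame["cluster_id"].to_numpy()
        est = MultilevelRegression().fit(X, y, groups=groups)
        assert est.coef_.shape == (2,)
        pred = est.predict(X[:5])
        np.testing.assert_allclose(pred, est.intercept_ + X[:5] @ est.coef_)

    def test_groups_required(self, floored_dataset):
        X = floored_dataset.frame[["x1", "x2"]].to_numpy()
        with pytest.raises(ValueError, match="groups"):
            MultilevelRegression().fit(X, floored_dataset.y_obs)


class TestWaldInference:
    @pytest.mark.parametrize(
        "est,se,sig",
        [
            (0.40, 0.19, True),   # z ~ 2.11
            (0.24, 0.25, False),  # z ~ 0.96
        ],
    )
    def test_significance_at_printed_cells(self, est, se, sig):
        fr = pd.DataFrame(
            {"cluster_id": [0, 1], "y_obs": [0.0, 1.0], "censored_low": False,
             "censored_high": False, "x1": [0.0, 1.0], "x2": [0.0, 1.0]}
        )
        from mltobit.model_core import FitResult
        names = ("effect",)
        fit = FitResult(
            method="naive_ml",
            estimates=pd.Series({"effect": est, "var_between": 0.1, "var_within": 1.0}),
            std_errors=pd.Series({"effect": se, "var_between": 0.1, "var_within": 0.1}),
            vcov=pd.DataFrame(np.eye(3)),
            loglik=0.0, converged=True, n_iter=1, n_obs=2, n_clusters=2,
            fixed_effect_names=names,
        )
        (res,) = wald_infer(fit)
        assert res.significant_at_005 is sig
        assert res.z_statistic == pytest.approx(est / se)
        assert bool(res.two_sided_p < 0.05) == sig

    def test_zero_estimate_gives_p_one(self):
        from mltobit.model_core import FitResult
        fit = FitResult(
            method="tobit",
            estimates=pd.Series({"effect": 0.0, "var_between": 0.1, "var_within": 1.0}),
            std_errors=pd.Series({"effect": 0.5, "var_between": 0.1, "var_within": 0.1}),
            vcov=pd.DataFrame(np.eye(3)),
            loglik=0.0, converged=True, n_iter=1, n_obs=2, n_clusters=2,
            fixed_effect_names=("effect",),
        )
        (res,) = wald_infer(fit)
        assert res.z_statistic == 0.0
        assert res.two_sided_p == pytest.approx(1.0)
        assert not res.significant_at_005
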