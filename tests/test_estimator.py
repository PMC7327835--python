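"""EM, imputation draws, Rubin pooling, parcels, and the one-factor fit."""

import numpy as np
import pandas as pd
import pytest

from threeform.estimator import (
    build_parcels,
    draw_imputations,
    em_mvn,
    fit_one_factor,
    fit_parcel_cfa,
    normal_theory_acov_vech,
    round_robin_parcels,
    rubin_pool,
    unvech,
    vech,
)
from threeform.exceptions import (
    EstimationError,
    InvalidInputError,
    InvalidSpecError,
    UnderIdentifiedError,
)


def _mvn_sample(rng, n, mean, cov):
    return pd.DataFrame(
        rng.multivariate_normal(mean, cov, size=n),
        columns=[f"v{k}" for k in range(len(mean))],
    )


def _three_form_mask(df, rng):
    """MCAR three-form mask: each row loses one of three column blocks."""
    out = df.copy()
    p = df.shape[1]
    blocks = np.array_split(np.arange(p), 3)
    which = rng.integers(3, size=len(df))
    for b, idx in enumerate(blocks):
        rows = np.flatnonzero(which == b)
        out.iloc[rows, idx] = np.nan
    return out


@pytest.fixture
def pop_cov(rng):
    A = rng.standard_normal((6, 6))
    cov = A @ A.T / 6 + np.eye(6)
    return cov


class TestEmMvn:
    def test_complete_data_closed_form(self, rng, pop_cov):
        df = _mvn_sample(rng, 200, np.zeros(6), pop_cov)
        est = em_mvn(df)
        X = df.to_numpy()
        assert np.allclose(est.mean, X.mean(axis=0))
        assert np.allclose(est.cov, np.cov(X.T, ddof=0))
        assert est.converged

    def test_loglik_monotone(self, rng, pop_cov):
        df = _three_form_mask(_mvn_sample(rng, 300, np.arange(6.0), pop_cov), rng)
        est = em_mvn(df)
        diffs = np.diff(est.loglik_path)
        assert (diffs >= -1e-7 * np.abs(est.loglik_path[:-1])).all()
        assert est.converged

    def test_mcar_recovery_within_sampling_error(self, rng, pop_cov):
        n = 2000
        mean = np.arange(6.0)
        df = _three_form_mask(_mvn_sample(rng, n, mean, pop_cov), rng)
        est = em_mvn(df)
        # 2/3 of each column observed; allow 3 MC SEs on each mean
        se_mean = np.sqrt(np.diag(pop_cov) / (n * 2 / 3))
        assert (np.abs(est.mean - mean) < 3 * se_mean).all()
        # covariance entries: normal-theory bound with the observed pair fraction
        for i in range(6):
            for j in range(6):
                frac = 2 / 3 if i == j else 1 / 3
                se_cov = np.sqrt(
                    (pop_cov[i, i] * pop_cov[j, j] + pop_cov[i, j] ** 2) / (n * frac)
                )
                assert abs(est.cov[i, j] - pop_cov[i, j]) < 3.5 * se_cov

    def test_consistency_as_n_grows(self, rng, pop_cov):
        errs = {}
        for n in (200, 500, 2000):
            maes = []
            for _ in range(4):
                df = _three_form_mask(_mvn_sample(rng, n, np.zeros(6), pop_cov), rng)
                est = em_mvn(df)
                maes.append(np.abs(est.cov - pop_cov).mean())
            errs[n] = np.mean(maes)
        assert errs[2000] < errs[500] < errs[200]

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(EstimationError):
            em_mvn(df)

    def test_warm_start_on_complete_data_converges_fast(self, rng, pop_cov):
        df = _mvn_sample(rng, 500, np.zeros(6), pop_cov)
        est = em_mvn(df, start=(np.zeros(6), pop_cov))
        # complete data: the M-step is a fixed point after one sweep
        assert est.n_iter <= 2
        assert em_mvn(df).n_iter <= 2


class TestDrawImputations:
    def test_no_missing_identical_copies(self, rng, pop_cov):
        df = _mvn_sample(rng, 50, np.zeros(6), pop_cov)
        est = em_mvn(df)
        imps = draw_imputations(df, est, 3, rng)
        for imp in imps:
            pd.testing.assert_frame_equal(imp, df)

    def test_observed_cells_untouched(self, rng, pop_cov):
        df = _three_form_mask(_mvn_sample(rng, 100, np.zeros(6), pop_cov), rng)
        est = em_mvn(df)
        imp = draw_imputations(df, est, 1, rng)[0]
        obs = df.notna()
        assert np.allclose(imp.to_numpy()[obs.to_numpy()], df.to_numpy()[obs.to_numpy()])
        assert not imp.isna().any().any()

    def test_fully_missing_row_uses_marginal(self, rng, pop_cov):
        df = _mvn_sample(rng, 60, np.zeros(6), pop_cov)
        df.iloc[0, :] = np.nan
        est = em_mvn(df)
        imps = draw_imputations(df, est, 400, rng)
        draws = np.array([imp.iloc[0].to_numpy() for imp in imps])
        se = np.sqrt(np.diag(est.cov) / len(imps))
        assert (np.abs(draws.mean(axis=0) - est.mean) < 4 * se).all()

    def test_conditional_mean_and_spread(self, rng):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        df = pd.DataFrame({"v0": np.zeros(200), "v1": np.full(200, np.nan)})
        df["v0"] = np.random.default_rng(3).standard_normal(200)
        est = em_mvn(pd.concat([df, _mvn_sample(rng, 500, np.zeros(2), cov)]))
        imps = draw_imputations(df, est, 100, rng)
        stack = np.array([imp["v1"].to_numpy() for imp in imps])  # M x n
        rho = est.cov[0, 1] / est.cov[0, 0]
        cond_mean = est.mean[1] + rho * (df["v0"].to_numpy() - est.mean[0])
        resid_var = est.cov[1, 1] - est.cov[0, 1] ** 2 / est.cov[0, 0]
        mc_se = np.sqrt(resid_var / len(imps))
        assert (np.abs(stack.mean(axis=0) - cond_mean) < 4.5 * mc_se).all()
        assert stack.std(axis=0).mean() == pytest.approx(np.sqrt(resid_var), rel=0.1)


class TestRubinPool:
    def test_single_imputation_degenerates(self):
        pooled = rubin_pool([1.5], [0.04])
        assert pooled.estimate[0] == 1.5
        assert pooled.between[0] == 0.0
        assert pooled.se[0] == pytest.approx(0.2)

    def test_hand_arithmetic(self):
        pooled = rubin_pool([1.0, 1.2], [0.04, 0.04])
        assert pooled.estimate[0] == pytest.approx(1.1)
        assert pooled.between[0] == pytest.approx(0.02)
        assert pooled.se[0] == pytest.approx(np.sqrt(0.04 + 1.5 * 0.02))

    def test_identical_estimates_zero_between(self):
        pooled = rubin_pool([2.0, 2.0, 2.0], [0.01, 0.01, 0.01])
        assert pooled.between[0] == 0.0
        assert pooled.se[0] == pytest.approx(0.1)
        assert np.isinf(pooled.df[0])

    def test_total_se_at_least_within(self, rng):
        q = rng.standard_normal((20, 5))
        u = rng.uniform(0.01, 0.1, size=(20, 5))
        pooled = rubin_pool(q, u)
        assert (pooled.se**2 >= pooled.within - 1e-12).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            rubin_pool([1.0, 2.0], [0.1])


class TestParcels:
    def test_round_robin_sizes(self):
        assert [len(g) for g in round_robin_parcels([f"i{k}" for k in range(12)])] == [4, 4, 4]
        assert [len(g) for g in round_robin_parcels([f"i{k}" for k in range(13)])] == [5, 4, 4]

    def test_constant_items_give_constant_parcel(self):
        df = pd.DataFrame({f"i{k}": np.full(5, 7.0) for k in range(6)})
        parcels = build_parcels(df, {"s": round_robin_parcels(list(df.columns))})
        assert np.allclose(parcels.to_numpy(), 7.0)
        assert list(parcels.columns) == ["s_p1", "s_p2", "s_p3"]

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"i0": [1.0], "i1": [2.0]})
        with pytest.raises(InvalidSpecError):
            build_parcels(df, {"s": [["i0"], ["i1"], []]})

    def test_wrong_group_count_rejected(self):
        df = pd.DataFrame({"i0": [1.0], "i1": [2.0]})
        with pytest.raises(InvalidSpecError):
            build_parcels(df, {"s": [["i0"], ["i1"]]})


class TestFitOneFactor:
    def test_rank_one_exact(self):
        lam = np.array([0.8, 0.6, 0.4])
        sol = fit_one_factor(np.outer(lam, lam))
        assert np.allclose(sol.loadings, lam, atol=1e-8)
        assert np.allclose(sol.residual_variances, 0.0, atol=1e-8)
        assert sol.admissible

    def test_analytic_recovery(self):
        lam = np.array([1.0, 1.0, 1.0])
        theta = np.array([0.5, 0.5, 0.5])
        sol = fit_one_factor(np.outer(lam, lam) + np.diag(theta))
        assert np.allclose(sol.loadings, lam, atol=1e-6)
        assert np.allclose(sol.residual_variances, theta, atol=1e-6)

    def test_four_indicator_uls(self):
        lam = np.array([0.9, 0.7, 0.6, 0.5])
        theta = np.array([0.3, 0.4, 0.5, 0.6])
        sol = fit_one_factor(np.outer(lam, lam) + np.diag(theta))
        assert sol.converged
        assert np.allclose(sol.loadings, lam, atol=1e-4)
        assert np.allclose(sol.residual_variances, theta, atol=1e-4)

    def test_heywood_flagged(self):
        S = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.5], [0.9, 0.5, 1.0]])
        sol = fit_one_factor(S)
        assert not sol.admissible
        assert (sol.residual_variances < 0).any()

    def test_under_identified_rejected(self):
        with pytest.raises(UnderIdentifiedError):
            fit_one_factor(np.eye(2))

    def test_sign_convention(self):
        lam = np.array([-0.8, -0.6, -0.4])
        sol = fit_one_factor(np.outer(lam, lam) + 0.2 * np.eye(3))
        assert sol.loadings[0] >= 0


class TestParcelCfa:
    def test_recovers_population_structure(self, rng):
        lam = {"f1": np.array([0.8, 0.7, 0.6]), "f2": np.array([0.9, 0.5, 0.6])}
        phi = 0.4
        p = 6
        S = np.zeros((p, p))
        S[:3, :3] = np.outer(lam["f1"], lam["f1"]) + np.diag([0.3, 0.4, 0.5])
        S[3:, 3:] = np.outer(lam["f2"], lam["f2"]) + np.diag([0.2, 0.6, 0.5])
        S[:3, 3:] = phi * np.outer(lam["f1"], lam["f2"])
        S[3:, :3] = S[:3, 3:].T
        cols = [f"f1_p{k}" for k in (1, 2, 3)] + [f"f2_p{k}" for k in (1, 2, 3)]
        fit = fit_parcel_cfa(
            pd.DataFrame(S, index=cols, columns=cols),
            n=500,
            parcel_cols_by_scale={"f1": cols[:3], "f2": cols[3:]},
        )
        assert fit.estimates["loading[f1,p1]"] == pytest.approx(0.8, abs=1e-8)
        assert fit.estimates["latcor[f1,f2]"] == pytest.approx(phi, abs=1e-8)
        assert all(v > 0 for k, v in fit.variances.items())

    def test_delta_se_matches_monte_carlo(self, rng):
        """Delta-method SEs agree with the empirical spread of the estimator."""
        lam = np.array([0.8, 0.7, 0.6])
        theta = np.array([0.36, 0.51, 0.64])
        Sigma = np.outer(lam, lam) + np.diag(theta)
        cols = ["f_p1", "f_p2", "f_p3"]
        n = 400
        ests, ses = [], []
        for _ in range(300):
            X = rng.multivariate_normal(np.zeros(3), Sigma, size=n)
            S = pd.DataFrame(np.cov(X.T, ddof=1), index=cols, columns=cols)
            fit = fit_parcel_cfa(S, n, {"f": cols})
            ests.append(fit.estimates["loading[f,p1]"])
            ses.append(np.sqrt(fit.variances["loading[f,p1]"]))
        assert np.mean(ses) == pytest.approx(np.std(ests), rel=0.15)

    def test_vech_roundtrip(self, rng):
        A = rng.standard_normal((5, 5))
        S = A @ A.T
        assert np.allclose(unvech(vech(S), 5), S)

    def test_acov_of_variance_entry(self):
        # var(s_ii) = 2 sigma_ii^2 / n under normality
        S = np.diag([2.0, 3.0])
        G = normal_theory_acov_vech(S, n=100)
        assert G[0, 0] == pytest.approx(2 * 4.0 / 100)
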