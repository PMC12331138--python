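import numpy as np
import pytest
from scipy import stats as sps

from transferknock import (
    AugmentedDesign,
    EnvironmentDataset,
    GaussianDesignModel,
    PriorInformation,
    combine_multi_priors,
    lasso_coefdiff_stats,
    pooled_coefficients,
    prior_weights_from_coefficients,
    sample_gaussian_knockoffs,
    weighted_lasso_stats,
)
from transferknock.statistics import _penalty_factors, _weighted_fit
from transferknock.utils import standardize_columns


def cd_lasso_oracle(Z, y, alphas, n_iter=3000):
    """Direct cyclic coordinate descent for per-feature l1 penalties.

    Solves min_b 1/(2n) ||y - c - Zb||^2 + sum_j alphas_j |b_j| from
    scratch; independent of the column-rescaling route in the package.
    """
    n, d = Z.shape
    c = y.mean()
    r = y - c
    b = np.zeros(d)
    col_sq = (Z**2).sum(axis=0) / n
    for _ in range(n_iter):
        for j in range(d):
            rho = Z[:, j] @ r / n + col_sq[j] * b[j]
            new = np.sign(rho) * max(abs(rho) - alphas[j], 0.0) / col_sq[j]
            if new != b[j]:
                r -= Z[:, j] * (new - b[j])
                b[j] = new
    return b


def make_augmented(n, p, seed, beta=None, noise=1.0, rho=0.5):
    model = GaussianDesignModel.from_ar1(p, rho)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p)) @ np.linalg.cholesky(model.covariance).T
    eps = noise * rng.standard_normal(n)
    y = eps if beta is None else X @ beta + eps
    return sample_gaussian_knockoffs(X, model, seed + 1), y


class TestLassoCoefdiff:
    def test_huge_penalty_gives_zero_statistics(self):
        design, y = make_augmented(60, 10, seed=0, beta=np.ones(10))
        W = lasso_coefdiff_stats(design, y, alpha=1e6, seed=1)
        np.testing.assert_array_equal(W.W, np.zeros(10))

    def test_strong_signal_is_positive_in_most_replicates(self):
        # one dominant signal: its statistic should come out positive
        # essentially always (>= 95% of seeded replicates)
        hits = 0
        reps = 100
        beta = np.zeros(20)
        beta[7] = 1.0
        for r in range(reps):
            design, y = make_augmented(500, 20, seed=100 + r, beta=beta, noise=1.0)
            W = lasso_coefdiff_stats(design, y, cv_folds=5, seed=r, n_alphas=20, eps=1e-2)
            hits += W.W[7] > 0
        assert hits >= 0.95 * reps

    def test_flip_sign_contract_at_fixed_penalty(self):
        design, y = make_augmented(120, 8, seed=3, beta=np.r_[np.ones(3), np.zeros(5)])
        kwargs = dict(alpha=0.02, seed=9, tol=1e-12)
        W = lasso_coefdiff_stats(design, y, **kwargs).W
        for j in (0, 5):
            W_swap = lasso_coefdiff_stats(design.swapped([j]), y, **kwargs).W
            assert W_swap[j] == pytest.approx(-W[j], abs=1e-7)
            others = np.delete(np.arange(8), j)
            np.testing.assert_allclose(W_swap[others], W[others], atol=1e-7)

    def test_deterministic_given_seed(self):
        design, y = make_augmented(80, 6, seed=4, beta=np.r_[1.0, np.zeros(5)])
        a = lasso_coefdiff_stats(design, y, cv_folds=4, seed=5)
        b = lasso_coefdiff_stats(design, y, cv_folds=4, seed=5)
        np.testing.assert_array_equal(a.W, b.W)
        assert a.meta["alpha"] == b.meta["alpha"]

    def test_rejects_constant_outcome_and_small_n(self):
        design, _ = make_augmented(30, 4, seed=6)
        with pytest.raises(ValueError, match="constant"):
            lasso_coefdiff_stats(design, np.ones(30))
        with pytest.raises(ValueError, match="cv_folds"):
            lasso_coefdiff_stats(design, np.arange(30.0), cv_folds=31)

    def test_binomial_family_runs_and_flips_sign(self):
        design, y = make_augmented(150, 5, seed=8, beta=np.r_[2.0, np.zeros(4)])
        yb = (y > np.median(y)).astype(float)
        W = lasso_coefdiff_stats(design, yb, family="binomial", cv_folds=4, seed=2)
        assert len(W.W) == 5 and np.isfinite(W.W).all()


class TestPriorWeights:
    def test_zero_coefficients_give_inverse_eps(self):
        phi = prior_weights_from_coefficients(np.zeros(10))
        np.testing.assert_allclose(phi, np.full(5, 20.0))

    def test_printed_formula_hand_value(self):
        coef = np.zeros(4)
        coef[0], coef[2] = 0.5, 0.15  # pair (b_0, b_{0+p}) with p=2
        phi = prior_weights_from_coefficients(coef)
        assert phi[0] == pytest.approx(1 / 0.7)
        assert phi[1] == pytest.approx(20.0)

    def test_monotone_decreasing_in_magnitude(self, rng):
        coef = rng.standard_normal(20)
        phi1 = prior_weights_from_coefficients(coef)
        phi2 = prior_weights_from_coefficients(2 * coef)
        assert np.all(phi2 < phi1)

    def test_without_knockoff_term(self):
        coef = np.r_[0.5, np.zeros(1)]
        phi = prior_weights_from_coefficients(coef, include_knockoffs=False)
        assert phi[0] == pytest.approx(1 / 0.55)

    def test_rejects_odd_length(self):
        with pytest.raises(ValueError, match="even"):
            prior_weights_from_coefficients(np.ones(5))


class TestCombineMultiPriors:
    def test_mean_properties(self, rng):
        v = rng.standard_normal(8)
        np.testing.assert_array_equal(combine_multi_priors([v]), v)
        np.testing.assert_allclose(
            combine_multi_priors([np.zeros(4), np.ones(4)]), np.full(4, 0.5)
        )
        np.testing.assert_allclose(combine_multi_priors([v, v, v]), v)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            combine_multi_priors([np.ones(4), np.ones(6)])


class TestWeightedLasso:
    def test_gamma_zero_grid_reduces_to_plain_lasso(self):
        design, y = make_augmented(100, 12, seed=10, beta=np.r_[np.ones(3), np.zeros(9)])
        phi = np.linspace(0.5, 3.0, 12)
        Ww = weighted_lasso_stats(design, y, phi, gamma_grid=(0.0,), cv_folds=5, seed=3)
        Wl = lasso_coefdiff_stats(design, y, cv_folds=5, seed=3)
        np.testing.assert_allclose(Ww.W, Wl.W, atol=1e-8)
        assert Ww.meta["gamma"] == 0.0

    def test_unit_phi_collapses_to_plain_lasso_via_tiebreak(self):
        design, y = make_augmented(90, 8, seed=11, beta=np.r_[np.ones(2), np.zeros(6)])
        Ww = weighted_lasso_stats(
            design, y, np.ones(8), gamma_grid=(0.0, 0.4, 0.9), cv_folds=4, seed=6
        )
        Wl = lasso_coefdiff_stats(design, y, cv_folds=4, seed=6)
        np.testing.assert_allclose(Ww.W, Wl.W, atol=1e-8)
        assert Ww.meta["gamma"] == 0.0  # ties broken toward smaller gamma

    def test_flip_sign_contract_at_fixed_tuning(self):
        design, y = make_augmented(110, 6, seed=12, beta=np.r_[1.0, np.zeros(5)])
        phi = np.linspace(0.4, 2.0, 6)
        kwargs = dict(phi=phi, fixed=(0.03, 0.6), seed=4, tol=1e-12)
        W = weighted_lasso_stats(design, y, **kwargs).W
        W_swap = weighted_lasso_stats(design.swapped([2]), y, **kwargs).W
        assert W_swap[2] == pytest.approx(-W[2], abs=1e-7)
        others = np.delete(np.arange(6), 2)
        np.testing.assert_allclose(W_swap[others], W[others], atol=1e-7)

    def test_column_rescaling_matches_coordinate_descent_oracle(self, rng):
        # per-feature penalties through rescaled columns must agree with a
        # direct coordinate-descent solve of the weighted objective
        design, y = make_augmented(50, 5, seed=13, beta=np.r_[1.0, 0.5, np.zeros(3)])
        Z = standardize_columns(design.XXt)
        phi = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        lam, gamma = 0.05, 0.7
        coef = _weighted_fit(Z, y, phi, gamma, lam, tol=1e-14)
        alphas = lam * np.tile(_penalty_factors(phi, gamma), 2)
        oracle = cd_lasso_oracle(Z, y, alphas)
        np.testing.assert_allclose(coef, oracle, atol=1e-6)

    def test_informative_weights_do_not_weaken_true_signals(self):
        # phi small on true signals should give statistics at least as
        # large there, on average, as the unweighted ones
        reps, p, k = 20, 40, 6
        beta = np.zeros(p)
        signals = np.arange(k)
        beta[signals] = 0.4
        diffs = []
        for r in range(reps):
            design, y = make_augmented(250, p, seed=300 + r, beta=beta)
            phi = np.where(np.isin(np.arange(p), signals), 0.2, 3.0)
            Ww = weighted_lasso_stats(
                design, y, phi, gamma_grid=(0.0, 0.5, 1.0),
                cv_folds=4, seed=r, n_alphas=20, eps=1e-2,
            )
            Wl = lasso_coefdiff_stats(design, y, cv_folds=4, seed=r, n_alphas=20, eps=1e-2)
            diffs.append(Ww.W[signals].mean() - Wl.W[signals].mean())
        assert np.mean(diffs) >= 0

    def test_rejects_invalid_phi_and_gamma(self):
        design, y = make_augmented(40, 4, seed=14)
        with pytest.raises(ValueError, match="strictly positive"):
            weighted_lasso_stats(design, y, np.array([1.0, -1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="gamma"):
            weighted_lasso_stats(design, y, np.ones(4), gamma_grid=(0.5, 1.2))


class TestPooledCoefficients:
    def _envs(self, n_envs, seed):
        model = GaussianDesignModel.from_ar1(6, 0.5)
        rng = np.random.default_rng(seed)
        out = []
        for e in range(n_envs):
            X = rng.standard_normal((60, 6))
            y = X[:, 0] + rng.standard_normal(60)
            d = EnvironmentDataset(X=X, y=y, env_id=e)
            d.knockoffs = sample_gaussian_knockoffs(X, model, seed + e).knockoffs
            out.append(d)
        return out

    def test_single_dataset_equals_direct_fit(self):
        # pooling a single environment adds no machinery: it must equal a
        # plain cross-validated lasso on that environment's augmented design
        envs = self._envs(1, seed=20)
        pooled = pooled_coefficients(envs, cv_folds=4, seed=1)
        Z = standardize_columns(envs[0].augmented.XXt)
        from sklearn.linear_model import LassoCV

        from transferknock.utils import PURPOSE, child_rng

        labels = child_rng(1, PURPOSE["cv_folds"], 0).permutation(np.arange(60) % 4)
        folds = [(np.flatnonzero(labels != k), np.flatnonzero(labels == k)) for k in range(4)]
        cv = LassoCV(alphas=100, cv=folds, tol=1e-4, precompute=True, max_iter=10000)
        cv.fit(Z, envs[0].y)
        np.testing.assert_allclose(pooled, cv.coef_, atol=1e-10)

    def test_order_invariance(self):
        envs = self._envs(3, seed=21)
        a = pooled_coefficients(envs, cv_folds=4, seed=2, tol=1e-10)
        b = pooled_coefficients(envs[::-1], cv_folds=4, seed=2, tol=1e-10)
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_duplicated_rows_leave_fixed_penalty_fit_unchanged(self):
        # the lasso objective is an average: duplicating every row leaves
        # the solution at a fixed penalty unchanged
        design, y = make_augmented(50, 5, seed=22, beta=np.r_[1.0, np.zeros(4)])
        double = AugmentedDesign(np.vstack([design.XXt, design.XXt]))
        W1 = lasso_coefdiff_stats(design, y, alpha=0.04, seed=7, tol=1e-12).W
        W2 = lasso_coefdiff_stats(double, np.r_[y, y], alpha=0.04, seed=7, tol=1e-12).W
        np.testing.assert_allclose(W1, W2, atol=1e-7)

    def test_rejects_empty_and_mismatched(self):
        with pytest.raises(ValueError, match="at least one"):
            pooled_coefficients([])
        envs = self._envs(1, seed=23)
        other = EnvironmentDataset(X=np.ones((10, 3)), y=np.arange(10.0), env_id=1)
        with pytest.raises(ValueError, match="disagree"):
            pooled_coefficients(envs + [other])


class TestNullSignSymmetry:
    @staticmethod
    def _null_sign_counts(phi_source, reps=50):
        """Signs of nonzero statistics at null coordinates, target fully null."""
        p = 20
        model = GaussianDesignModel.from_ar1(p, 0.5)
        pos = tot = 0
        for r in range(reps):
            rng = np.random.default_rng(5000 + r)
            X0 = rng.standard_normal((120, p))
            y0 = rng.standard_normal(120)  # global null in the target
            aug0 = sample_gaussian_knockoffs(X0, model, 600 + r)
            Xe = rng.standard_normal((120, p))
            beta = np.zeros(p)
            beta[:5] = 0.5
            ye = Xe @ beta + rng.standard_normal(120)
            ext = EnvironmentDataset(X=Xe, y=ye, env_id=1)
            ext.knockoffs = sample_gaussian_knockoffs(Xe, model, 700 + r).knockoffs
            if phi_source == "external":
                coefs = pooled_coefficients([ext], cv_folds=4, seed=r, n_alphas=20, eps=1e-2)
            else:  # pooled across all environments sharing the null set
                tgt = EnvironmentDataset(X=X0, y=y0, env_id=0)
                tgt.knockoffs = aug0.knockoffs
                ye_null = rng.standard_normal(120)
                ext_null = EnvironmentDataset(X=Xe, y=ye_null, env_id=1)
                ext_null.knockoffs = ext.knockoffs
                coefs = pooled_coefficients(
                    [tgt, ext_null], cv_folds=4, seed=r, n_alphas=20, eps=1e-2
                )
            phi = prior_weights_from_coefficients(coefs)
            # fixed tuning keeps plenty of nonzero statistics under the
            # global null (cross-validation would zero almost all of them)
            W = weighted_lasso_stats(aug0, y0, phi, fixed=(0.02, 0.6), seed=r).W
            nz = W != 0
            pos += int(np.sum(W[nz] > 0))
            tot += int(np.sum(nz))
        return pos, tot

    @pytest.mark.parametrize("phi_source", ["external", "pooled"])
    def test_null_statistic_signs_are_fair_coin_flips(self, phi_source):
        pos, tot = self._null_sign_counts(phi_source)
        assert tot >= 100
        pval = sps.binomtest(pos, tot, 0.5).pvalue
        assert pval > 1e-3


class TestGlobalNullSignSymmetry:
    def test_lasso_statistic_signs_under_global_null(self):
        # y independent of X: nonzero statistic signs across replicates
        # should be indistinguishable from fair coin flips
        p = 60
        model = GaussianDesignModel.from_ar1(p, 0.5)
        pos = tot = 0
        r = 0
        while tot < 500:
            rng = np.random.default_rng(9000 + r)
            X = rng.standard_normal((150, p))
            y = rng.standard_normal(150)
            aug = sample_gaussian_knockoffs(X, model, 950 + r)
            W = lasso_coefdiff_stats(aug, y, alpha=0.02, seed=r).W
            nz = W != 0
            pos += int(np.sum(W[nz] > 0))
            tot += int(np.sum(nz))
            r += 1
        assert sps.binomtest(pos, tot, 0.5).pvalue > 1e-3
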