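import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline

import bdlim
from bdlim.exceptions import (
    CollinearityError,
    ComparabilityError,
    IdentifiabilityError,
    IncompleteFitError,
    InvalidSpecError,
    UnidentifiableExposureError,
)
from bdlim.model import (
    BDLIMSpec,
    build_weight_basis,
    compare_patterns,
    compute_dic,
    fit_bdlim,
    select_weight_df,
)

from _utils import exact_posterior_summaries, fit_simulated


def _mcse(draws):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        ess = float(az.ess(np.asarray(draws)))
    return np.std(draws) / np.sqrt(max(ess, 1.0))


class TestWeightBasis:
    @pytest.mark.parametrize("T,K", [(40, 4), (40, 2), (40, 8), (20, 5)])
    def test_full_rank(self, T, K):
        B = build_weight_basis(T, K)
        assert B.shape == (T, K)
        assert np.linalg.matrix_rank(B) == K

    def test_identifiability_errors(self):
        with pytest.raises(IdentifiabilityError):
            build_weight_basis(40, 40)
        with pytest.raises(IdentifiabilityError):
            build_weight_basis(40, 1)

    @pytest.mark.parametrize("K", [3, 4, 6, 8])
    def test_spans_natural_cubic_splines(self, K):
        """Column space equals that of an independently built natural-spline
        basis (scipy CubicSpline with natural boundary conditions through
        unit vectors at the same knots); compared via projection matrices."""
        T = 40
        B = build_weight_basis(T, K)
        knots = np.linspace(1.0, T, K)
        t = np.arange(1, T + 1, dtype=float)
        cols = []
        for j in range(K):
            e = np.zeros(K)
            e[j] = 1.0
            cols.append(CubicSpline(knots, e, bc_type="natural")(t))
        B2 = np.column_stack(cols)

        def projector(M):
            Q, _ = np.linalg.qr(M)
            return Q @ Q.T

        np.testing.assert_allclose(projector(B), projector(B2), atol=1e-10)


def _conjugate_problem(seed=5, n=300, T=40):
    rng = np.random.default_rng(seed)
    X = rng.normal(10, 3, (n, T))
    Z = np.c_[np.ones(n), rng.normal(0, 1, (n, 2))]
    w = np.zeros(T)
    w[30:40] = 1.0
    w /= np.linalg.norm(w)
    y = Z @ np.array([0.5, 0.3, -0.2]) + 0.1 * (X @ w) + rng.normal(0, 1, n)
    return y, X, Z, w


class TestFitBdlim:
    def test_fixed_weights_match_ols(self):
        """With the weight function held fixed the model is a plain linear
        regression; the posterior mean of beta must agree with OLS on the
        weighted-exposure column within 2 Monte Carlo standard errors."""
        y, X, Z, w = _conjugate_problem()
        spec = BDLIMSpec(pattern="n", n_iter=12_000, burn_in=2_000, thin=5, seed=3)
        fit = fit_bdlim(y, X, Z, None, spec, fixed_weights={"shared": w})
        beta = fit.beta[fit.groups[0]]
        D = np.c_[Z, X @ w]
        ols = np.linalg.lstsq(D, y, rcond=None)[0]
        assert abs(beta.mean() - ols[-1]) < 2 * _mcse(beta)
        # gamma agrees too (same tolerance per coefficient)
        for j in range(Z.shape[1]):
            assert abs(fit.gamma[:, j].mean() - ols[j]) < 3 * _mcse(fit.gamma[:, j])

    def test_fixed_weights_match_exact_posterior(self):
        """Tighter conjugate-limit check against a quadrature oracle for the
        exact semi-conjugate posterior."""
        y, X, Z, w = _conjugate_problem()
        spec = BDLIMSpec(pattern="n", n_iter=22_000, burn_in=2_000, thin=1, seed=4)
        fit = fit_bdlim(y, X, Z, None, spec, fixed_weights={"shared": w})
        oracle = exact_posterior_summaries(
            y, np.c_[Z, X @ w], spec.prior_effect_var,
            spec.prior_sigma_shape, spec.prior_sigma_scale,
        )
        beta = fit.beta[fit.groups[0]]
        assert abs(beta.mean() - oracle["theta_mean"][-1]) < 2 * _mcse(beta)
        assert abs(fit.sigma2.mean() - oracle["sigma2_mean"]) < 3 * _mcse(fit.sigma2)

    def test_unidentifiable_exposure(self):
        n, T = 50, 40
        X = np.full((n, T), 10.0)
        y = np.random.default_rng(0).normal(size=n)
        with pytest.raises(UnidentifiableExposureError):
            fit_bdlim(y, X, np.ones((n, 1)), None, BDLIMSpec(pattern="n"))

    def test_rank_deficient_covariates(self):
        rng = np.random.default_rng(0)
        n = 60
        X = rng.normal(10, 3, (n, 40))
        Z = np.ones((n, 2))  # duplicated intercept
        with pytest.raises(CollinearityError):
            fit_bdlim(rng.normal(size=n), X, Z, None, BDLIMSpec(pattern="n"))

    def test_group_required_for_interaction_patterns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(10, 3, (30, 40))
        with pytest.raises(InvalidSpecError):
            fit_bdlim(
                rng.normal(size=30), X, np.ones((30, 1)), None, BDLIMSpec(pattern="bw")
            )

    def test_draw_invariants(self, bw_fit):
        """Every retained weight draw is unit norm with nonnegative sum
        (the sign convention), and sigma2 draws are positive."""
        for g in bw_fit.groups:
            norms = np.linalg.norm(bw_fit.weights[g], axis=1)
            np.testing.assert_allclose(norms, 1.0, atol=1e-10)
            assert (bw_fit.weights[g].sum(axis=1) >= -1e-10).all()
        assert (bw_fit.sigma2 > 0).all()

    def test_shared_pattern_objects_identical(self, zscored):
        _, df, exposures, _ = zscored
        from bdlim.model import SPIROMETRY_ADJUSTMENT, build_covariate_design

        Z = build_covariate_design(df, SPIROMETRY_ADJUSTMENT)
        spec = BDLIMSpec(pattern="n", n_iter=1500, burn_in=500, thin=5, seed=1)
        fit = fit_bdlim(
            df["z_fev1"].to_numpy(), exposures, Z, df["sex"].to_numpy(), spec
        )
        assert fit.weights["boy"] is fit.weights["girl"]
        assert fit.beta["boy"] is fit.beta["girl"]

    def test_nonconvergence_flagged_not_raised(self, zscored):
        """A too-short chain yields a convergence flag and warning, not an
        error."""
        from bdlim.model import SPIROMETRY_ADJUSTMENT, build_covariate_design

        _, df, exposures, _ = zscored
        Z = build_covariate_design(df, SPIROMETRY_ADJUSTMENT)
        # 99 retained draws bounds the effective sample size below 100
        spec = BDLIMSpec(pattern="bw", n_iter=695, burn_in=200, thin=5, seed=5)
        with pytest.warns(RuntimeWarning, match="effective sample size"):
            fit = fit_bdlim(
                df["z_fev1"].to_numpy(), exposures, Z, df["sex"].to_numpy(), spec
            )
        assert fit.converged is False

    def test_scale_equivariance(self):
        """Multiplying all exposures by c multiplies beta by 1/c and leaves
        the weights unchanged, within Monte Carlo error."""
        rng = np.random.default_rng(2)
        n, T = 500, 40
        X = rng.normal(10, 3, (n, T))
        w_true = np.zeros(T)
        w_true[30:40] = 1 / np.sqrt(10)
        y = 0.3 * (X @ w_true) + rng.normal(0, 1, n)
        Z = np.ones((n, 1))
        spec = BDLIMSpec(pattern="n", weight_df=6, n_iter=6000, burn_in=2000, thin=5, seed=9)
        fit1 = fit_bdlim(y, X, Z, None, spec)
        fit2 = fit_bdlim(y, 2.0 * X, Z, None, spec)
        g = fit1.groups[0]
        b1, b2 = fit1.beta[g], fit2.beta[g]
        assert abs(b1.mean() - 2.0 * b2.mean()) < 2 * (_mcse(b1) + 2 * _mcse(b2))
        assert np.allclose(
            fit1.weights[g].mean(axis=0), fit2.weights[g].mean(axis=0), atol=0.05
        )

    def test_pattern_n_ignores_group_permutation(self):
        """Pattern n collapses the groups: permuting the labels changes the
        cumulative effect only within Monte Carlo error."""
        rng = np.random.default_rng(3)
        n, T = 500, 40
        X = rng.normal(10, 3, (n, T))
        w_true = np.zeros(T)
        w_true[30:40] = 1 / np.sqrt(10)
        y = 0.3 * (X @ w_true) + rng.normal(0, 1, n)
        Z = np.ones((n, 1))
        group = np.array(["boy", "girl"])[rng.integers(0, 2, n)]
        perm = rng.permutation(group)
        spec = BDLIMSpec(pattern="n", weight_df=6, n_iter=6000, burn_in=2000, thin=5, seed=10)
        ce = []
        for gvec in (group, perm):
            fit = fit_bdlim(y, X, Z, gvec, spec)
            draws = bdlim.lag_effect_draws(fit, fit.groups[0]).sum(axis=1)
            ce.append((draws.mean(), _mcse(draws)))
        assert abs(ce[0][0] - ce[1][0]) < 3 * (ce[0][1] + ce[1][1])

    def test_lag_curve_recovery_correlation(self):
        """Single contiguous strong window: the posterior-mean lag curve
        correlates > 0.9 with the truth (median over 10 seeds)."""
        corrs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, T = 1000, 40
            X = np.asarray(
                bdlim.generate_exposures(bdlim.TruthSpec(n_children=n, seed=seed + 600))
            )
            truth = np.zeros(T)
            truth[29:40] = -0.5 / 11
            y = X @ truth + rng.normal(0, 1, n)
            mspec = BDLIMSpec(
                pattern="n", weight_df=6, n_iter=4000, burn_in=2000, thin=5, seed=seed
            )
            f = fit_bdlim(y, X, np.ones((n, 1)), None, mspec)
            curve = bdlim.lag_effect_draws(f, f.groups[0]).mean(axis=0)
            corrs.append(np.corrcoef(curve, truth)[0, 1])
        assert np.median(corrs) > 0.9


class TestDic:
    def test_duplicating_draws_leaves_dic_unchanged(self, bw_fit):
        rec = compute_dic(bw_fit)
        doubled = dataclasses.replace(
            bw_fit,
            weights={g: np.vstack([w, w]) for g, w in bw_fit.weights.items()},
            beta={g: np.concatenate([b, b]) for g, b in bw_fit.beta.items()},
            gamma=np.vstack([bw_fit.gamma, bw_fit.gamma]),
            sigma2=np.concatenate([bw_fit.sigma2, bw_fit.sigma2]),
            log_likelihood=np.concatenate(
                [bw_fit.log_likelihood, bw_fit.log_likelihood]
            ),
        )
        rec2 = compute_dic(doubled)
        for key in ("D_bar", "p_D", "DIC"):
            assert rec2[key] == pytest.approx(rec[key], abs=1e-9)

    def test_conjugate_model_matches_exact_dic(self):
        """On a fixed-weight (purely conjugate) model the sampler DIC agrees
        with a quadrature-exact computation within 1% of p_D."""
        y, X, Z, w = _conjugate_problem()
        spec = BDLIMSpec(pattern="n", n_iter=42_000, burn_in=2_000, thin=1, seed=9)
        fit = fit_bdlim(y, X, Z, None, spec, fixed_weights={"shared": w})
        rec = compute_dic(fit)
        oracle = exact_posterior_summaries(
            y, np.c_[Z, X @ w], spec.prior_effect_var,
            spec.prior_sigma_shape, spec.prior_sigma_scale,
        )
        assert abs(rec["DIC"] - oracle["DIC"]) < 0.01 * oracle["p_D"]
        assert abs(rec["p_D"] - oracle["p_D"]) < 0.01 * oracle["p_D"]

    def test_effective_parameters_positive(self):
        """p_D is positive on well-identified simulations across seeds."""
        pds = []
        for seed in range(10):
            _, fit = fit_simulated(
                seed + 40,
                pattern="n",
                n=1000,
                boy_ce=-0.4,
                girl_ce=-0.4,
                boy_window=(30, 40),
                girl_window=(30, 40),
                n_iter=1500,
                burn_in=500,
            )
            pds.append(compute_dic(fit)["p_D"])
        assert all(p > 0 for p in pds)

    def test_missing_trace_errors(self, bw_fit):
        short = dataclasses.replace(bw_fit, log_likelihood=bw_fit.log_likelihood[:50])
        with pytest.raises(IncompleteFitError):
            compute_dic(short)


class TestComparePatterns:
    def _fake_fits(self, bw_fit, dics):
        fits = {}
        for pat, dic in zip(("n", "b", "w", "bw"), dics):
            fits[pat] = dataclasses.replace(
                bw_fit, dic={"D_bar": dic, "p_D": 0.0, "DIC": dic}
            )
        return fits

    def test_equal_dic_gives_uniform_weights(self, bw_fit):
        tab = compare_patterns(self._fake_fits(bw_fit, [100.0] * 4))
        np.testing.assert_allclose(tab["weight"], 0.25)

    def test_weight_formula(self, bw_fit):
        tab = compare_patterns(self._fake_fits(bw_fit, [100.0, 102.0, 104.0, 106.0]))
        expected = np.exp(-0.5 * np.array([0.0, 2.0, 4.0, 6.0]))
        expected /= expected.sum()
        np.testing.assert_allclose(tab["weight"], expected, atol=1e-3)
        assert tab["weight"].sum() == pytest.approx(1.0)
        assert tab.loc[tab["best"], "pattern"].iloc[0] == "n"

    def test_mismatched_data_error(self, bw_fit):
        other = dataclasses.replace(bw_fit, y=bw_fit.y[:-5], dic={"D_bar": 0, "p_D": 0, "DIC": 0})
        with pytest.raises(ComparabilityError):
            compare_patterns({"n": bw_fit, "b": other})


class TestSelectWeightDf:
    def test_singleton_grid(self, zscored):
        _, df, exposures, _ = zscored
        from bdlim.model import SPIROMETRY_ADJUSTMENT, build_covariate_design

        Z = build_covariate_design(df, SPIROMETRY_ADJUSTMENT)
        spec = BDLIMSpec(pattern="n", n_iter=1500, burn_in=500, thin=5, seed=2)
        best, trace = select_weight_df(
            df["z_fev1"].to_numpy(), exposures, Z, None, [3], spec
        )
        assert best == 3
        assert len(trace) == 1

    def test_trace_matches_independent_grid(self, zscored):
        """The returned DIC trace reproduces independently tabulated
        per-K fits run with the same seeds."""
        _, df, exposures, _ = zscored
        from bdlim.model import SPIROMETRY_ADJUSTMENT, build_covariate_design

        Z = build_covariate_design(df, SPIROMETRY_ADJUSTMENT)
        y = df["z_fev1"].to_numpy()
        spec = BDLIMSpec(pattern="n", n_iter=1500, burn_in=500, thin=5, seed=2)
        grid = [3, 4, 5]
        best, trace = select_weight_df(y, exposures, Z, None, grid, spec)
        manual = []
        for K in grid:
            f = fit_bdlim(y, exposures, Z, None, dataclasses.replace(spec, weight_df=K))
            manual.append(compute_dic(f)["DIC"])
        np.testing.assert_allclose(trace["DIC"], manual, atol=1e-9)
        assert best == grid[int(np.argmin(manual))]

    def test_empty_grid(self, zscored):
        _, df, exposures, _ = zscored
        with pytest.raises(InvalidSpecError):
            select_weight_df(
                df["z_fev1"].to_numpy(), exposures, np.ones((len(df), 1)), None, [],
                BDLIMSpec(pattern="n"),
            )
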