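"""Factor modeling: standardization, EFA, CFA spec building, DWLS fit,
fit statistics, pruning, and model selection."""

import numpy as np
import pytest
from scipy import optimize

from gibnet import factors
from gibnet.factors import (
    CfaSpec,
    EfaSolution,
    FactorModel,
    FitStats,
    build_cfa_spec,
    compute_fit_stats,
    fit_cfa,
    prune_nonsignificant,
    run_efa,
    select_best_model,
    smooth_to_pd,
    standardize_to_correlation,
)
from gibnet.ldsc import GeneticCovariance, vech_indices


def _gencov(s, v_off=1e-4, labels=None, v=None):
    """Covariance container with a standardized-style V: zero-variance diagonal."""
    s = np.asarray(s, float)
    p = s.shape[0]
    labels = labels or [f"y{i+1}" for i in range(p)]
    if v is None:
        e = p * (p + 1) // 2
        diag = np.array([0.0 if i == j else v_off for (i, j) in vech_indices(p)])
        v = np.diag(diag)
    return GeneticCovariance(labels=labels, s=s, v=v, n_blocks=10, m=1000)


def _model_cov(lam, phi):
    lam = np.asarray(lam, float)
    phi = np.asarray(phi, float)
    r = lam @ phi @ lam.T
    np.fill_diagonal(r, 1.0)
    return r


class TestStandardize:
    def test_two_by_two_hand_arithmetic(self):
        p = 2
        e = 3
        gc = GeneticCovariance(["a", "b"], np.array([[4.0, 1.0], [1.0, 1.0]]),
                               np.eye(e) * 1e-4, n_blocks=10, m=100)
        out = standardize_to_correlation(gc)
        assert out.s[0, 1] == pytest.approx(1.0 / np.sqrt(4.0))
        np.testing.assert_allclose(np.diag(out.s), 1.0)

    def test_unit_diagonal_input_unchanged(self):
        s = np.array([[1.0, 0.3], [0.3, 1.0]])
        gc = GeneticCovariance(["a", "b"], s, np.eye(3) * 1e-4, n_blocks=10, m=100)
        np.testing.assert_allclose(standardize_to_correlation(gc).s, s)

    def test_nonpositive_diagonal_names_phenotype(self):
        gc = GeneticCovariance(["a", "bad"], np.array([[1.0, 0.0], [0.0, -0.1]]),
                               np.eye(3) * 1e-4, n_blocks=10, m=100)
        with pytest.raises(ValueError, match="bad"):
            standardize_to_correlation(gc)

    def test_delta_v_matches_monte_carlo_oracle(self):
        # sample s-vectors from N(theta, V), standardize each, compare
        # the empirical covariance of the correlations to the delta-method V
        rng = np.random.default_rng(0)
        s = np.array([[0.30, 0.08, 0.05],
                      [0.08, 0.25, 0.06],
                      [0.05, 0.06, 0.35]])
        p = 3
        idx = vech_indices(p)
        theta = np.array([s[i, j] for i, j in idx])
        a = rng.standard_normal((len(idx), len(idx))) * 0.004
        v = a @ a.T + np.eye(len(idx)) * 1e-5
        gc = GeneticCovariance([f"y{i}" for i in range(p)], s, v, n_blocks=10, m=100)
        out = standardize_to_correlation(gc)

        draws = theta + rng.multivariate_normal(np.zeros(len(idx)), v, size=200_000)
        corrs = np.empty_like(draws)
        for e, (i, j) in enumerate(idx):
            ii = idx.index((i, i))
            jj = idx.index((j, j))
            corrs[:, e] = draws[:, e] / np.sqrt(draws[:, ii] * draws[:, jj])
        emp = np.cov(corrs.T)
        off = [e for e, (i, j) in enumerate(idx) if i != j]
        np.testing.assert_allclose(out.v[np.ix_(off, off)], emp[np.ix_(off, off)],
                                   rtol=0.08, atol=2e-6)
        # unit diagonal has (near) zero sampling variance
        diag = [e for e, (i, j) in enumerate(idx) if i == j]
        assert np.all(np.diag(out.v)[diag] < 1e-20)


class TestSmoothToPd:
    def test_pd_input_bitwise_unchanged(self):
        r = np.array([[1.0, 0.4], [0.4, 1.0]])
        out = smooth_to_pd(r)
        assert out is r

    def test_indefinite_correlation_clipped_diagonal_restored(self):
        r = np.array([[1.0, 1.2], [1.2, 1.0]])
        out = smooth_to_pd(r)
        assert np.linalg.eigvalsh(out).min() >= 1e-8
        np.testing.assert_allclose(np.diag(out), 1.0)
        np.testing.assert_allclose(out, out.T)


class TestEfa:
    def test_identity_correlation_has_no_common_factor(self):
        gc = _gencov(np.eye(12))
        sols = run_efa(gc, k_range=[1])
        assert np.all(np.abs(sols[0].loadings) < 0.1)

    def test_two_factor_structure_recovered(self):
        lam = np.zeros((12, 2))
        lam[:6, 0] = 0.7
        lam[6:, 1] = 0.7
        phi = np.array([[1.0, 0.3], [0.3, 1.0]])
        gc = _gencov(_model_cov(lam, phi))
        sol = [s for s in run_efa(gc, k_range=[2]) if s.k == 2][0]
        # factor congruence up to sign and permutation
        cong = np.abs(
            (sol.loadings / np.linalg.norm(sol.loadings, axis=0)).T
            @ (lam / np.linalg.norm(lam, axis=0))
        )
        best = np.maximum(cong.max(axis=0), cong.max(axis=1))
        assert np.all(best >= 0.95)

    def test_k_not_below_p_enforced(self):
        gc = _gencov(np.eye(12))
        with pytest.raises(ValueError):
            run_efa(gc, k_range=range(1, 13))

    def test_eigenvalues_non_increasing(self, demo_gencov):
        corr = standardize_to_correlation(demo_gencov["odd"])
        sol = run_efa(corr, k_range=[2])[0]
        assert np.all(np.diff(sol.eigenvalues) <= 1e-12)


def _efa_from_loadings(loadings, labels=None):
    loadings = np.asarray(loadings, float)
    p, k = loadings.shape
    return EfaSolution(
        k=k,
        labels=labels or [f"y{i+1}" for i in range(p)],
        loadings=loadings,
        phi=np.eye(k),
        eigenvalues=np.arange(p, 0, -1.0),
        rotation="promax",
    )


class TestBuildCfaSpec:
    def test_threshold_is_strict(self):
        efa = _efa_from_loadings([[0.31, 0.0], [0.6, 0.0], [0.0, 0.29],
                                  [0.0, 0.6], [0.0, 0.7], [0.35, 0.0]])
        spec = build_cfa_spec(efa, tau=0.3)
        assert "y1" in spec.factor_map["F1"]     # 0.31 kept
        assert "y3" not in spec.factor_map["F2"]  # 0.29 dropped

    def test_cross_loading_retained_on_both_factors(self):
        efa = _efa_from_loadings([[0.6, 0.6], [0.5, 0.0], [0.0, 0.5],
                                  [0.4, 0.0], [0.0, 0.4]])
        spec = build_cfa_spec(efa, tau=0.3)
        assert "y1" in spec.factor_map["F1"] and "y1" in spec.factor_map["F2"]

    def test_single_region_factor_removed(self):
        efa = _efa_from_loadings([[0.6, 0.0], [0.5, 0.0], [0.0, 0.6], [0.4, 0.0]])
        spec = build_cfa_spec(efa, tau=0.3)
        assert spec.n_factors == 1  # second factor had one region only

    def test_no_surviving_factor_is_error(self):
        efa = _efa_from_loadings([[0.1, 0.0], [0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(ValueError):
            build_cfa_spec(efa, tau=0.5)


class TestFitCfa:
    def test_exact_data_recovers_parameters_with_zero_fmin(self):
        lam = np.array([[0.8], [0.7], [0.6]])
        r = _model_cov(lam, np.eye(1))
        spec = CfaSpec({"F1": ("y1", "y2", "y3")}, 0.3)
        model = fit_cfa(spec, _gencov(r))
        assert model.converged
        assert model.fmin == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(model.lambda_est[:, 0], lam[:, 0], atol=1e-4)
        np.testing.assert_allclose(model.theta, 1 - lam[:, 0] ** 2, atol=1e-4)

    def test_matches_independent_nelder_mead_oracle(self):
        lam = np.array([[0.8], [0.7], [0.6]])
        r = _model_cov(lam, np.eye(1))
        # perturb the off-diagonals so the fit is non-trivial
        r[0, 1] = r[1, 0] = r[0, 1] + 0.05
        r[1, 2] = r[2, 1] = r[1, 2] - 0.04
        gc = _gencov(r, v_off=2e-4)
        spec = CfaSpec({"F1": ("y1", "y2", "y3")}, 0.3)
        model = fit_cfa(spec, gc)

        idx = vech_indices(3)
        w = np.array([0.0 if i == j else 1 / 2e-4 for (i, j) in idx])
        svec = np.array([r[i, j] for i, j in idx])

        def oracle_f(x):
            l = x[:, None]
            common = l @ l.T
            theta = np.clip(1.0 - np.diag(common), 0.0, None)
            sig = common + np.diag(theta)
            resid = svec - np.array([sig[i, j] for i, j in idx])
            return float(np.sum(w * resid**2))

        res = optimize.minimize(oracle_f, np.array([0.5, 0.5, 0.5]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14,
                                         "maxiter": 10_000})
        np.testing.assert_allclose(model.lambda_est[:, 0], res.x, atol=1e-4)
        assert model.fmin == pytest.approx(res.fun, abs=1e-8)

    def test_parameter_recovery_on_synthetic_panel(self, demo_model, demo_truth):
        assert demo_model.k == 2
        est = demo_model.lambda_est
        true = demo_truth.lambda_true
        # align factor order by congruence
        c = np.abs(est.T @ true)
        perm = c.argmax(axis=1)
        rmse = np.sqrt(np.mean((est[:, np.argsort(perm)] - true) ** 2))
        assert rmse < 0.1

    def test_unknown_region_in_spec_is_error(self):
        spec = CfaSpec({"F1": ("y1", "nope")}, 0.3)
        with pytest.raises(ValueError, match="nope"):
            fit_cfa(spec, _gencov(np.eye(3)))


class TestFitStats:
    def test_perfect_fit_has_zero_srmr_unit_cfi(self):
        lam = np.array([[0.8], [0.7], [0.6]])
        gc = _gencov(_model_cov(lam, np.eye(1)))
        spec = CfaSpec({"F1": ("y1", "y2", "y3")}, 0.3)
        model = fit_cfa(spec, gc)
        fit = compute_fit_stats(model, gc)
        assert fit.srmr == pytest.approx(0.0, abs=1e-6)
        assert fit.cfi == pytest.approx(1.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fit.df == 0  # 6 unique moments, 3 loadings + 3 residuals free

    def test_srmr_hand_computed_on_2x2(self):
        # residual 0.1 on the single off-diagonal of a 2x2 correlation:
        # rms over the 3 unique elements = sqrt(0.1^2 / 3)
        lam = np.array([[0.6], [0.5]])
        implied = _model_cov(lam, np.eye(1))
        observed = implied.copy()
        observed[0, 1] = observed[1, 0] = implied[0, 1] + 0.1
        assert factors.srmr(observed, implied) == pytest.approx(np.sqrt(0.1**2 / 3), rel=1e-9)

    def test_useless_extra_parameter_raises_aic_by_two(self):
        lam = np.zeros((4, 2))
        lam[:2, 0] = [0.8, 0.7]
        lam[2:, 1] = [0.8, 0.7]
        gc = _gencov(_model_cov(lam, np.array([[1.0, 0.2], [0.2, 1.0]])))
        spec1 = CfaSpec({"F1": ("y1", "y2"), "F2": ("y3", "y4")}, 0.3)
        spec2 = CfaSpec({"F1": ("y1", "y2", "y3"), "F2": ("y3", "y4")}, 0.3)
        m1 = fit_cfa(spec1, gc)
        m2 = fit_cfa(spec2, gc)  # true cross-loading is zero
        f1 = compute_fit_stats(m1, gc)
        f2 = compute_fit_stats(m2, gc)
        assert f2.aic - f1.aic == pytest.approx(2.0, abs=1e-3)

    def test_negative_df_rejected(self):
        with pytest.raises(ValueError):
            FitStats(chi2=1.0, df=-1, aic=1.0, cfi=1.0, srmr=0.0, n_free_params=10)


class TestPruning:
    def test_all_significant_is_fixed_point(self, demo_model, demo_corr_even):
        pruned = prune_nonsignificant(demo_model, demo_corr_even)
        assert pruned.spec.factor_map == demo_model.spec.factor_map

    def test_true_zero_cross_loading_removed(self):
        rng = np.random.default_rng(7)
        lam = np.zeros((6, 2))
        lam[:3, 0] = [0.8, 0.7, 0.6]
        lam[3:, 1] = [0.8, 0.7, 0.6]
        r = _model_cov(lam, np.array([[1.0, 0.3], [0.3, 1.0]]))
        noise = rng.standard_normal(r.shape) * 0.005
        noise = np.triu(noise, 1)
        r = r + noise + noise.T
        gc = _gencov(smooth_to_pd(r), v_off=1e-4)
        spec = CfaSpec({"F1": ("y1", "y2", "y3", "y4"), "F2": ("y4", "y5", "y6")}, 0.3)
        model = fit_cfa(spec, gc)
        model.fit = compute_fit_stats(model, gc)
        pruned = prune_nonsignificant(model, gc)
        assert "y4" not in pruned.spec.factor_map["F1"]
        assert pruned.k <= model.k  # pruning never adds factors


def _dummy_model(aic, k, n_free):
    lam = np.full((2 * max(k, 1), k), 0.5)
    spec = CfaSpec({f"F{i+1}": (f"y{2*i+1}", f"y{2*i+2}") for i in range(k)}, 0.3)
    m = FactorModel(
        spec=spec, labels=[f"y{i+1}" for i in range(2 * k)],
        factor_names=list(spec.factor_map), lambda_est=lam,
        lambda_se=np.full_like(lam, 0.1), phi=np.eye(k), phi_se=np.zeros((k, k)),
        theta=np.full(2 * k, 0.5), theta_se=np.zeros(2 * k), converged=True,
    )
    m.fit = FitStats(chi2=aic - 2 * n_free, df=0, aic=aic, cfi=1.0, srmr=0.0,
                     n_free_params=n_free)
    return m


class TestSelection:
    def test_minimum_aic_wins(self):
        models = [_dummy_model(12.0, 1, 2), _dummy_model(10.0, 2, 3), _dummy_model(11.0, 3, 4)]
        assert select_best_model(models) is models[1]

    def test_aic_tie_broken_toward_fewer_factors(self):
        models = [_dummy_model(10.0, 3, 5), _dummy_model(10.0, 2, 5)]
        assert select_best_model(models) is models[1]

    def test_no_converged_candidate_is_error(self):
        m = _dummy_model(10.0, 2, 5)
        m.converged = False
        with pytest.raises(ValueError):
            select_best_model([m])


class TestSplitHalfConsistency:
    def test_selected_model_refits_on_odd_half(self, demo_model, demo_gencov):
        corr_odd = standardize_to_correlation(demo_gencov["odd"])
        refit = fit_cfa(demo_model.spec, corr_odd)
        for i, f in demo_model.free_loadings():
            se = np.hypot(demo_model.lambda_se[i, f], refit.lambda_se[i, f])
            assert abs(demo_model.lambda_est[i, f] - refit.lambda_est[i, f]) < 3 * se
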