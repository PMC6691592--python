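import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from lcsm.data_io import LongitudinalDataset
from lcsm.model_zoo import build_mutualism_lcs, design_from_data
from lcsm.sem_core import (
    CompiledModel,
    IdentificationError,
    ModelSpec,
    Param,
    PatternData,
    StructuralCycleError,
    cross_sample_z,
    fiml_loglik,
    fit,
    fit_baseline,
    fit_indices,
    fixed,
    free,
    implied_moments,
    likelihood_ratio_test,
    rmsea,
    rmsea_ci,
    saturated_moments,
    standardize,
)
from lcsm.synthetic_data import mutualism_generating_preset, simulate_dataset


def _toy_spec():
    """x -> y with coefficient b, exogenous variance 1, residual psi."""
    return ModelSpec(
        "toy",
        ("x", "y"),
        ("x", "y"),
        paths={("x", "y"): free("b", 0.0)},
        covariances={("x", "x"): fixed(1.0), ("y", "y"): free("psi", 1.0)},
        means={"x": free("mx", 0.0), "y": free("my", 0.0)},
    )


class TestImpliedMoments:
    def test_no_paths_unit_variances_gives_identity(self):
        spec = ModelSpec(
            "iid",
            ("a", "b"),
            ("a", "b"),
            covariances={("a", "a"): fixed(1.0), ("b", "b"): fixed(1.0)},
        )
        mu, sigma = implied_moments(spec, {})
        np.testing.assert_allclose(sigma, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(mu, 0.0, atol=1e-12)

    def test_single_path_hand_algebra(self):
        mu, sigma = implied_moments(_toy_spec(), {"b": 0.7, "psi": 0.5, "mx": 1.0, "my": 2.0})
        # var(y) = b^2 + psi, cov(x,y) = b, E[y] = my + b mx
        np.testing.assert_allclose(sigma, [[1.0, 0.7], [0.7, 0.7**2 + 0.5]], atol=1e-12)
        np.testing.assert_allclose(mu, [1.0, 2.7], atol=1e-12)

    def test_mutualism_moments_match_structural_recursion_oracle(self):
        """Independent oracle: simulate the latent change score recursion
        directly (levels, changes, measurement error drawn explicitly) and
        compare the empirical moments with the RAM-algebra implied moments."""
        cfg = mutualism_generating_preset(0.3, 227, seed=3)
        v = dict(cfg.true_values)
        des = cfg.design
        dA, dB = des.domains
        rng = np.random.default_rng(99)
        n = 400_000
        cov1 = np.array(
            [
                [v[f"var_{dA}_T1"], v[f"cov_{dA}_{dB}_T1"]],
                [v[f"cov_{dA}_{dB}_T1"], v[f"var_{dB}_T1"]],
            ]
        )
        lev = rng.multivariate_normal(
            [v[f"mean_{dA}_T1"], v[f"mean_{dB}_T1"]], cov1, size=n
        )
        A = {dA: [lev[:, 0]], dB: [lev[:, 1]]}
        zc = np.array(
            [
                [v[f"zeta_{dA}"], v["psi_change_contemp"]],
                [v["psi_change_contemp"], v[f"zeta_{dB}"]],
            ]
        )
        for k, w in enumerate(("T2", "T3")):
            res = rng.multivariate_normal([0, 0], zc, size=n)
            alpha_a = v[f"alpha_{dA}_{w}"]
            ch_a = (
                alpha_a
                + v[f"beta_{dA}"] * A[dA][k]
                + v[f"gamma_{dB}_to_{dA}"] * A[dB][k]
                + res[:, 0]
            )
            ch_b = (
                v[f"alpha_{dB}"]
                + v[f"beta_{dB}"] * A[dB][k]
                + v[f"gamma_{dA}_to_{dB}"] * A[dA][k]
                + res[:, 1]
            )
            A[dA].append(A[dA][k] + ch_a)
            A[dB].append(A[dB][k] + ch_b)
        obs = []
        for d in (dA, dB):
            for k, w in enumerate(des.wave_labels):
                e = rng.normal(0, math.sqrt(des.residual(d, w)), n)
                obs.append(A[d][k] + e)
        Y = np.column_stack(obs)
        mu, sigma = cfg.implied()
        np.testing.assert_allclose(Y.mean(axis=0), mu, atol=0.06)
        np.testing.assert_allclose(np.cov(Y, rowvar=False), sigma, rtol=0.03, atol=0.15)

    def test_cycle_raises_structural_error(self):
        spec = ModelSpec(
            "cyclic",
            ("a", "b"),
            ("a", "b"),
            paths={("a", "b"): fixed(1.0), ("b", "a"): fixed(1.0)},
            covariances={("a", "a"): fixed(1.0), ("b", "b"): fixed(1.0)},
        )
        with pytest.raises(StructuralCycleError):
            implied_moments(spec, {})


class TestFimlLoglik:
    def test_complete_data_equals_joint_mvn_logdensity(self, mutualism_cfg, mutualism_data):
        values = dict(mutualism_cfg.true_values)
        mu, sigma = mutualism_cfg.implied()
        Y = mutualism_data.to_matrix(list(mutualism_cfg.spec.observed))
        expected = stats.multivariate_normal.logpdf(Y, mu, sigma).sum()
        got = fiml_loglik(mutualism_cfg.spec, values, mutualism_data)
        assert got == pytest.approx(expected, abs=1e-8 * abs(expected))

    def test_fully_missing_person_contributes_zero(self):
        spec = _toy_spec()
        vals = {"b": 0.5, "psi": 1.0, "mx": 0.0, "my": 0.0}
        Y = np.array([[0.3, -0.2], [1.0, 0.5]])
        Y_aug = np.vstack([Y, [np.nan, np.nan]])
        with pytest.warns(UserWarning, match="no observed scores"):
            aug = fiml_loglik(spec, vals, Y_aug)
        assert aug == pytest.approx(fiml_loglik(spec, vals, Y), abs=1e-12)

    def test_partial_row_equals_brute_force_marginalization(self):
        """One missing entry: FIML must equal the log of the density with the
        missing coordinate integrated out numerically."""
        spec = _toy_spec()
        vals = {"b": 0.8, "psi": 0.6, "mx": 0.5, "my": -0.3}
        mu, sigma = implied_moments(spec, vals)
        x_obs = 0.9
        joint = stats.multivariate_normal(mu, sigma)
        marg, _ = integrate.quad(
            lambda y: joint.pdf([x_obs, y]), -40, 40, epsabs=1e-12, epsrel=1e-12
        )
        got = fiml_loglik(spec, vals, np.array([[x_obs, np.nan]]))
        assert got == pytest.approx(math.log(marg), abs=1e-8)


class TestSaturatedAndFit:
    def test_saturated_fit_reproduces_sample_moments(self, mutualism_data, mutualism_cfg):
        Y = mutualism_data.to_matrix(list(mutualism_cfg.spec.observed))
        pat = PatternData(Y)
        mu, sigma, ll = saturated_moments(pat)
        np.testing.assert_allclose(mu, Y.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(sigma, np.cov(Y, rowvar=False, ddof=0), atol=1e-6)

    def test_saturated_moments_with_missing_match_direct_optimum(self):
        """EM solution beats / matches any nearby perturbation in FIML."""
        cfg = mutualism_generating_preset(0.2, 120, seed=5, missing_rate=0.2)
        Y = simulate_dataset(cfg).to_matrix(list(cfg.spec.observed))
        pat = PatternData(Y)
        mu, sigma, ll = saturated_moments(pat)
        rng = np.random.default_rng(0)
        for _ in range(5):
            dmu = mu + rng.normal(0, 0.05, mu.shape)
            dsig = sigma + 0.05 * np.diag(rng.random(len(mu)))
            assert pat.loglik(dmu, dsig) <= ll + 1e-6

    def test_self_consistency_recovers_exact_moment_point(self):
        """If the sample moments equal some parameter point's implied moments,
        the fit recovers that point and chisq is ~0."""
        spec = _toy_spec()
        truth = {"b": 0.6, "psi": 0.8, "mx": 0.2, "my": 1.0}
        mu, sigma = implied_moments(spec, truth)
        rng = np.random.default_rng(7)
        Y = rng.multivariate_normal(mu, sigma, size=500)
        # transform the draw to have exactly the implied moments
        Yc = Y - Y.mean(axis=0)
        L_emp = np.linalg.cholesky(np.cov(Yc, rowvar=False, ddof=0))
        L_tgt = np.linalg.cholesky(sigma)
        Y_exact = Yc @ np.linalg.inv(L_emp).T @ L_tgt.T + mu
        f = fit(spec, Y_exact)
        assert f.converged
        assert f.chisq == pytest.approx(0.0, abs=1e-4)
        for k, v in truth.items():
            assert f.estimates[k] == pytest.approx(v, abs=1e-4)

    def test_parameter_recovery_n1000_within_3se(self):
        cfg = mutualism_generating_preset(0.3, 1000, seed=17)
        data = simulate_dataset(cfg)
        design = design_from_data(data, reliabilities=cfg.design.reliabilities)
        f = fit(build_mutualism_lcs(design), data)
        assert f.converged
        for label in (
            "beta_vocabulary",
            "beta_reasoning",
            "gamma_vocabulary_to_reasoning",
            "gamma_reasoning_to_vocabulary",
            "zeta_vocabulary",
            "zeta_reasoning",
            "psi_change_contemp",
            "cov_vocabulary_reasoning_T1",
        ):
            est, se = f.estimates[label], f.standard_errors[label]
            assert abs(est - cfg.true_values[label]) < 3 * se, label

    def test_coupling_bias_small_over_replicates(self):
        """Median absolute bias of the coupling estimates stays below 0.02
        on the raw scale across repeated draws at the study's sample size."""
        reps = 200
        biases_ab, biases_ba = [], []
        for r in range(reps):
            cfg = mutualism_generating_preset(0.3, 227, seed=30_000 + r)
            data = simulate_dataset(cfg)
            design = design_from_data(data, reliabilities=cfg.design.reliabilities)
            f = fit(build_mutualism_lcs(design), data, compute_se=False, standardized=False)
            if not f.converged:
                continue
            biases_ab.append(
                f.estimates["gamma_vocabulary_to_reasoning"]
                - cfg.true_values["gamma_vocabulary_to_reasoning"]
            )
            biases_ba.append(
                f.estimates["gamma_reasoning_to_vocabulary"]
                - cfg.true_values["gamma_reasoning_to_vocabulary"]
            )
        assert len(biases_ab) >= 0.95 * reps
        assert abs(np.median(biases_ab)) < 0.02
        assert abs(np.median(biases_ba)) < 0.02

    def test_refuses_more_parameters_than_persons(self, mutualism_cfg):
        small = simulate_dataset(mutualism_cfg.with_seed(5))
        tiny = LongitudinalDataset(
            small.scores.iloc[:10].reset_index(drop=True),
            small.wave_labels,
            small.domain_labels,
        )
        with pytest.raises(IdentificationError, match="free parameters"):
            fit(mutualism_cfg.spec, tiny)

    def test_aic_ordering_invariant_to_consistent_scaling(self, mutualism_data, mutualism_cfg):
        from lcsm.model_zoo import build_gfactor_lcs

        rel = mutualism_cfg.design.reliabilities
        d1 = design_from_data(mutualism_data, reliabilities=rel)
        f_m = fit(build_mutualism_lcs(d1), mutualism_data, compute_se=False, standardized=False)
        f_g = fit(build_gfactor_lcs(d1), mutualism_data, compute_se=False, standardized=False)

        scaled = LongitudinalDataset(
            mutualism_data.scores * 0.1,
            mutualism_data.wave_labels,
            mutualism_data.domain_labels,
        )
        d2 = design_from_data(scaled, reliabilities=rel)
        g_m = fit(build_mutualism_lcs(d2), scaled, compute_se=False, standardized=False)
        g_g = fit(build_gfactor_lcs(d2), scaled, compute_se=False, standardized=False)
        assert (f_m.aic < f_g.aic) == (g_m.aic < g_g.aic)
        assert (f_m.bic < f_g.bic) == (g_m.bic < g_g.bic)
        # chisq itself is scale-free
        assert f_m.chisq == pytest.approx(g_m.chisq, abs=0.05)


class TestStandardize:
    def test_unit_variance_path_is_unchanged(self):
        spec = _toy_spec()
        Y = np.random.default_rng(3).multivariate_normal([0, 0], np.eye(2), 400)
        f = fit(spec, Y)
        b = f.estimates["b"]
        sd_x = 1.0  # fixed exogenous variance
        sd_y = math.sqrt(b**2 + f.estimates["psi"])
        assert f.standardized["x->y"] == pytest.approx(b * sd_x / sd_y, abs=1e-8)

    def test_covariances_become_correlations(self, mutualism_data, mutualism_design):
        f = fit(build_mutualism_lcs(mutualism_design), mutualism_data)
        std = standardize(f)
        for key, val in std.items():
            if "~~" in key:
                a, b = key.split("~~")
                if a != b and np.isfinite(val):
                    assert -1.0001 <= val <= 1.0001, key


class TestFitIndices:
    @pytest.mark.parametrize(
        "chisq,df,n,expected",
        [(9.849, 8, 227, 0.032), (18.72, 9, 227, 0.069)],
    )
    def test_rmsea_matches_published_statistics(self, chisq, df, n, expected):
        assert round(rmsea(chisq, df, n), 3) == expected

    def test_rmsea_zero_when_chisq_at_or_below_df(self):
        assert rmsea(8.0, 8, 227) == 0.0
        assert rmsea(5.0, 8, 227) == 0.0

    def test_rmsea_ci_brackets_point_estimate(self):
        lo, hi = rmsea_ci(9.849, 8, 227)
        point = rmsea(9.849, 8, 227)
        assert lo <= point <= hi
        assert lo == pytest.approx(0.0, abs=1e-6)

    def test_full_indices_on_fitted_model(self, mutualism_data, mutualism_design):
        f = fit(build_mutualism_lcs(mutualism_design), mutualism_data)
        base = fit_baseline(f.spec, mutualism_data)
        idx = fit_indices(f, base, data=mutualism_data)
        assert idx.df == 8
        assert 0 <= idx.rmsea < 0.1
        assert 0.9 < idx.cfi <= 1.0
        assert 0 <= idx.srmr < 0.1
        assert idx.aic < idx.bic  # ln(227) > 2


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self, mutualism_data, mutualism_design):
        f = fit(build_mutualism_lcs(mutualism_design), mutualism_data,
                compute_se=False, standardized=False)
        res = likelihood_ratio_test(f, f)
        assert res.delta_chisq == 0.0
        assert res.delta_df == 0


class TestCrossSampleZ:
    def test_equal_estimates_give_zero(self):
        assert cross_sample_z(0.4, 0.05, 0.4, 0.08) == 0.0

    def test_direct_formula_example(self):
        assert cross_sample_z(0.5, 0.1, 0.2, 0.1) == pytest.approx(2.121, abs=5e-4)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            cross_sample_z(0.1, 0.0, 0.2, 0.1)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        b1=st.floats(-0.3, 0.3),
        b2=st.floats(-0.3, 0.3),
        s1=st.floats(0.02, 0.1),
        s2=st.floats(0.02, 0.1),
    )
    def test_fisher_variant_agrees_for_small_effects(self, b1, b2, s1, s2):
        """The Fisher-transformed z deviates from the plain z by O(beta^2):
        the arctanh numerator stretches by ~beta^2/3 while the delta-method
        SE stretches by ~beta^2, so relative disagreement is bounded by
        ~1.2 max(beta)^2 over this grid."""
        plain = cross_sample_z(b1, s1, b2, s2)
        fisher = cross_sample_z(b1, s1, b2, s2, fisher=True)
        tol = 0.005 + 1.2 * max(b1**2, b2**2) * abs(plain)
        assert fisher == pytest.approx(plain, abs=tol)


class TestSpecSerialization:
    def test_text_round_trip_preserves_structure(self, mutualism_design):
        spec = build_mutualism_lcs(mutualism_design)
        back = ModelSpec.from_text(spec.to_text())
        assert back.variables == spec.variables
        assert back.observed == spec.observed
        assert back.free_labels == spec.free_labels
        assert back.n_free == spec.n_free
        mu1, s1 = implied_moments(spec, spec.start_values())
        mu2, s2 = implied_moments(back, back.start_values())
        np.testing.assert_allclose(s1, s2, atol=1e-12)
        np.testing.assert_allclose(mu1, mu2, atol=1e-12)
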