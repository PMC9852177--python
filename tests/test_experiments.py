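"""Synthetic generators, leverage diagnostics, experiment drivers."""

import json

import numpy as np
import pytest

from twsketch import (
    bootstrap_enlarge,
    default_epsilon_grid,
    embedding_prob_tw,
    experiment_convergence,
    experiment_embedding,
    gen_ar1_gaussian,
    gen_diluted_outliers,
    gen_regression,
    leverage_scores,
)


class TestAR1Generator:
    def test_sample_covariance_matches_ar1(self):
        # entries (j, j+1) of the sample covariance -> rho within 4 SEs
        n, d, rho = 100_000, 50, 0.5
        X = gen_ar1_gaussian(n, d, rho=rho, seed=11)
        C = (X.T @ X) / n
        lag1 = np.diag(C, k=1)
        se = (1 + rho**2) / np.sqrt(n)  # conservative SE for a covariance entry
        assert np.abs(lag1 - rho).max() < 4 * se
        assert np.abs(np.diag(C) - 1.0).max() < 4 * np.sqrt(2 / n)

    def test_rho_zero_is_iid(self):
        X = gen_ar1_gaussian(50_000, 5, rho=0.0, seed=2)
        C = (X.T @ X) / 50_000
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 4 / np.sqrt(50_000)

    def test_reproducible(self):
        assert np.array_equal(
            gen_ar1_gaussian(100, 4, seed=9), gen_ar1_gaussian(100, 4, seed=9)
        )

    def test_rho_domain(self):
        with pytest.raises(ValueError):
            gen_ar1_gaussian(10, 2, rho=1.0)


class TestRegressionGenerator:
    def test_zero_noise_lies_in_column_space(self):
        X, y = gen_regression(300, 5, noise_sd=0.0, seed=4)
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.linalg.norm(y - X @ beta) < 1e-9

    def test_shapes(self):
        X, y = gen_regression(100, 7, seed=0)
        assert X.shape == (100, 7)
        assert y.shape == (100,)

    def test_n_le_d_rejected(self):
        with pytest.raises(ValueError):
            gen_regression(5, 5)


class TestLeverage:
    def test_identity_columns(self):
        A = np.eye(10)[:, :4]
        lp = leverage_scores(A)
        assert np.allclose(lp.scores[:4], 1.0)
        assert np.allclose(lp.scores[4:], 0.0)
        assert lp.max_score == 1.0

    def test_sum_equals_rank_full(self, rng):
        lp = leverage_scores(rng.standard_normal((100, 5)))
        assert lp.sum_score == pytest.approx(5.0, abs=1e-10)

    def test_sum_equals_rank_deficient(self, rng):
        a = rng.standard_normal(40)
        lp = leverage_scores(np.column_stack([a, 2 * a, -a]))
        assert lp.sum_score == pytest.approx(1.0, abs=1e-10)

    def test_max_at_least_average(self, rng):
        lp = leverage_scores(rng.standard_normal((200, 8)))
        assert lp.max_score >= 8 / 200

    def test_gaussian_bulk_has_flat_leverage(self):
        lp = leverage_scores(gen_ar1_gaussian(10_000, 10, seed=3))
        assert lp.max_score < 0.05

    def test_outlier_design_leverage_decays(self):
        small = leverage_scores(gen_diluted_outliers(2**12, 20, seed=1))
        large = leverage_scores(gen_diluted_outliers(2**15, 20, seed=1))
        assert small.max_score > 0.5
        assert large.max_score < small.max_score / 2


class TestBootstrap:
    def test_shape_and_columns(self, rng):
        A = rng.standard_normal((30, 4))
        B = bootstrap_enlarge(A, factor=10, seed=0)
        assert B.shape == (300, 4)
        # every bootstrap row is one of the original rows
        assert all(np.abs(A - row).max(axis=1).min() < 1e-15 for row in B[:20])

    def test_spreads_leverage(self):
        A = gen_diluted_outliers(128, 4, n_outliers=1, outlier_scale=64.0, seed=5)
        before = leverage_scores(A).max_score
        after = leverage_scores(bootstrap_enlarge(A, factor=10, seed=6)).max_score
        assert after < before + 1e-9

    def test_factor_validation(self, rng):
        with pytest.raises(ValueError):
            bootstrap_enlarge(rng.standard_normal((5, 2)), factor=0)


class TestEmbeddingDriver:
    def test_gaussian_report(self):
        rep = experiment_embedding(d=20, k=400, family="gaussian", B=1000, seed=8)
        assert rep.kind == "embedding"
        assert np.all(np.diff(rep.empirical) >= 0)
        assert np.all(np.diff(rep.theoretical) >= 0)
        assert 0 <= rep.sup_distance <= 0.12  # finite-d bias + B=1000 noise
        json.dumps(rep.to_dict())  # serializable

    def test_sketched_families_need_n(self):
        with pytest.raises(ValueError, match="n"):
            experiment_embedding(d=5, k=50, family="clarkson_woodruff", B=10)

    def test_esd_step_attached(self):
        rep = experiment_embedding(
            d=8, k=64, family="hadamard", B=50, n=256, seed=0,
            row_sampling="without_replacement", include_esd_step=True,
        )
        assert "sigma_star" in rep.extras
        step = rep.extras["esd_step"]
        assert set(np.unique(step)) <= {0.0, 1.0}

    def test_reproducible(self):
        a = experiment_embedding(d=5, k=50, family="gaussian", B=100, seed=3)
        b = experiment_embedding(d=5, k=50, family="gaussian", B=100, seed=3)
        assert np.array_equal(a.empirical, b.empirical)

    def test_default_grid_spans_tw_band(self):
        g = default_epsilon_grid(400, 20)
        p = embedding_prob_tw(g, 400, 20)
        assert float(p[0]) == pytest.approx(0.001, abs=1e-6)
        assert float(p[-1]) == pytest.approx(0.999, abs=1e-6)


class TestUniversalityOnFlatLeverageData:
    def test_ar1_design_is_already_at_the_gaussian_limit(self):
        # with flat leverage profiles the structured sketches match the
        # Gaussian distortion law at both desk-scale sample sizes: the KS
        # distance stays at the two-sample noise floor (~0.04 at these B)
        from scipy.stats import ks_2samp

        from twsketch import SketchSpec, simulate_gaussian_distortions, sketch_distortions

        d, k, B = 20, 400, 300
        ref = simulate_gaussian_distortions(k, d, 1000, seed=21)
        for n in (2**12, 2**15):
            A = gen_ar1_gaussian(n, d, seed=22)
            s = sketch_distortions(A, SketchSpec(family="clarkson_woodruff", k=k), B, seed=23)
            assert ks_2samp(s.draws, ref.draws).statistic < 0.12


class TestConvergenceDriver:
    def test_gaussian_sweep(self):
        rep = experiment_convergence(
            n=500, d=5, k_grid=[8, 25, 250], family="gaussian", R=20, seed=4
        )
        assert rep.empirical[0] <= rep.empirical[-1]
        assert rep.empirical[-1] == 1.0
        assert rep.extras["standard_errors"].shape == (3,)
        json.dumps(rep.to_dict())

    def test_uniform_fails_on_high_leverage(self):
        # the expected-failure baseline: uniform subsampling rarely yields a
        # contraction where the Gaussian sketch almost always does
        from twsketch import empirical_convergence_prob, gen_diluted_outliers

        A = gen_diluted_outliers(512, 4, n_outliers=1, outlier_scale=64.0, seed=0)
        y = A @ np.ones(4)
        p_unif, _ = empirical_convergence_prob(A, y, "uniform", k=64, R=20, seed=1)
        p_gauss, _ = empirical_convergence_prob(A, y, "gaussian", k=64, R=20, seed=2)
        assert p_gauss - p_unif > 0.5
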