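"""Closed-form Tracy-Widom constants, probabilities, and spectral limits."""

import numpy as np
import pytest

from twsketch import (
    convergence_half_prob_k,
    convergence_prob_tw,
    embedding_prob_tw,
    embedding_quantile_tw,
    esd_embedding_prob,
    esd_limits,
    max_eig_constants,
    min_eig_constants,
    simulate_wishart_extreme_eigs,
    vershynin_bound,
)


class TestMaxEigConstants:
    def test_frozen_values(self):
        # direct arithmetic: mu = (sqrt(399.5)+sqrt(19.5))^2/400,
        # sigma = mu-part * (1/sqrt(399.5)+1/sqrt(19.5))^(1/3)
        c = max_eig_constants(400, 20)
        assert c.mu_plus == pytest.approx(1.4888120, abs=1e-6)
        assert c.sigma_plus == pytest.approx(0.0397449, abs=1e-6)

    def test_symmetric_case_closed_form(self):
        k = 7
        c = max_eig_constants(k, k)
        rk = np.sqrt(k - 0.5)
        assert c.mu_plus == pytest.approx(4 * (k - 0.5) / k, rel=1e-12)
        assert c.sigma_plus == pytest.approx((2 * rk / k) * (2 / rk) ** (1 / 3), rel=1e-12)

    def test_concentration_limit(self):
        # k -> inf at fixed d: mu -> 1, sigma -> 0
        c = max_eig_constants(10_000_000, 5)
        assert c.mu_plus == pytest.approx(1.0, abs=2e-3)
        assert c.sigma_plus < 1e-3

    def test_domain(self):
        with pytest.raises(ValueError):
            max_eig_constants(5, 6)
        with pytest.raises(ValueError):
            max_eig_constants(5, 0)


class TestMinEigConstants:
    def test_frozen_values(self):
        c = min_eig_constants(400, 20)
        assert c.mu_minus == pytest.approx(242.47521, abs=1e-3)
        assert c.tau == pytest.approx(0.0360179, abs=1e-6)
        assert c.nu == pytest.approx(-0.5007272, abs=1e-6)

    def test_tau_positive_convention(self):
        for k, d in [(50, 5), (400, 20), (2000, 100)]:
            c = min_eig_constants(k, d)
            assert c.tau > 0
            assert c.sigma_minus > 0

    def test_limits_and_sign(self):
        # nu < 0 always (mu_minus < k); both nu, tau -> 0 as k grows
        c1 = min_eig_constants(100, 5)
        c2 = min_eig_constants(100_000, 5)
        assert c1.nu < 0 and c2.nu < 0
        assert abs(c2.nu) < abs(c1.nu)
        assert c2.tau < c1.tau

    def test_k_equal_d_rejected(self):
        with pytest.raises(ValueError):
            min_eig_constants(20, 20)


class TestEmbeddingProb:
    def test_at_centering_point_gives_f1_zero(self):
        c = max_eig_constants(400, 20)
        assert embedding_prob_tw(c.mu_plus - 1.0, 400, 20) == pytest.approx(0.8319, abs=1e-3)

    def test_limits(self):
        assert embedding_prob_tw(10.0, 400, 20) > 1 - 1e-6
        assert embedding_prob_tw(1e-4, 400, 20) < 1e-6

    def test_monotone_in_epsilon(self):
        eps = np.linspace(0.2, 0.9, 50)
        vals = embedding_prob_tw(eps, 400, 20)
        assert np.all(np.diff(vals) >= 0)

    def test_monotone_in_k_at_moderate_epsilon(self):
        vals = [float(embedding_prob_tw(0.5, k, 20)) for k in (300, 400, 600, 1000)]
        assert np.all(np.diff(vals) > 0)

    def test_epsilon_domain(self):
        with pytest.raises(ValueError):
            embedding_prob_tw(0.0, 400, 20)


class TestEmbeddingQuantile:
    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_roundtrip(self, p):
        eps = embedding_quantile_tw(p, 400, 20)
        assert float(embedding_prob_tw(eps, 400, 20)) == pytest.approx(p, abs=1e-6)

    def test_decreasing_in_k(self):
        qs = [embedding_quantile_tw(0.5, k, 20) for k in (300, 500, 1000, 2000)]
        assert np.all(np.diff(qs) < 0)

    def test_upper_tail_shrinks_with_d_at_fixed_ratio(self):
        # at k = 20 d the high-confidence quantile moves left as d grows
        # (the curves steepen around the common centering point)
        assert embedding_quantile_tw(0.9, 2000, 100) < embedding_quantile_tw(0.9, 400, 20)

    def test_p_domain(self):
        with pytest.raises(ValueError):
            embedding_quantile_tw(1.0, 400, 20)


class TestConvergenceProb:
    def test_high_ratio_is_near_one(self):
        assert convergence_prob_tw(400, 20) > 0.999

    def test_tends_to_one(self):
        assert convergence_prob_tw(100_000, 20) > 1 - 1e-9

    def test_monotone_in_k(self):
        vals = [convergence_prob_tw(k, 20) for k in (150, 180, 210, 260, 400)]
        assert np.all(np.diff(vals) > 0)

    def test_half_probability_crossing(self):
        k_half = convergence_half_prob_k(20)
        assert convergence_prob_tw(k_half, 20) >= 0.5
        assert convergence_prob_tw(k_half - 1, 20) < 0.5

    def test_matches_wishart_monte_carlo(self):
        # Pr(lambda_min > 1/2) by simulation within 4 binomial SEs of the
        # closed form, at a (k, d) where the probability is interior
        k, d, B = 195, 20, 1000
        lam_min, _ = simulate_wishart_extreme_eigs(k, d, B, seed=17)
        p_mc = float(np.mean(lam_min > 0.5))
        p_tw = convergence_prob_tw(k, d)
        assert 0.1 < p_tw < 0.9
        se = np.sqrt(p_mc * (1 - p_mc) / B)
        assert abs(p_mc - p_tw) < 4 * se

    def test_k_le_d_rejected(self):
        with pytest.raises(ValueError):
            convergence_prob_tw(20, 20)


class TestSpectralLimits:
    def test_reference_configuration(self):
        # d=50, k=1000, n=5000: direct arithmetic on the edge formulas
        lim = esd_limits(gamma=0.01, xi=0.2, alpha=0.05)
        assert lim.lambda_min_limit == pytest.approx((np.sqrt(0.99) - 0.2) ** 2, rel=1e-12)
        assert lim.lambda_max_limit == pytest.approx((np.sqrt(0.99) + 0.2) ** 2, rel=1e-12)
        assert lim.sigma_star == pytest.approx(0.4279950, abs=1e-6)

    def test_xi_to_one_collapse(self):
        lim = esd_limits(gamma=0.1, xi=1 - 1e-12, alpha=0.2)
        assert lim.lambda_min_limit == pytest.approx(0.9, abs=1e-5)
        assert lim.lambda_max_limit == pytest.approx(0.9, abs=1e-5)
        assert lim.sigma_star == pytest.approx(0.1, abs=1e-5)

    def test_small_alpha_collapse(self):
        lim = esd_limits(gamma=0.05, xi=0.5, alpha=1e-14)
        assert lim.lambda_min_limit == pytest.approx(0.95, abs=1e-6)
        assert lim.lambda_max_limit == pytest.approx(0.95, abs=1e-6)

    @pytest.mark.parametrize(
        "gamma,xi,alpha", [(0.0, 0.5, 0.5), (0.2, 0.1, 0.5), (0.1, 0.5, 1.5), (1.0, 0.5, 0.5)]
    )
    def test_domain(self, gamma, xi, alpha):
        with pytest.raises(ValueError):
            esd_limits(gamma, xi, alpha)

    def test_step_function(self):
        lim = esd_limits(0.01, 0.2, 0.05)
        assert esd_embedding_prob(lim.sigma_star, lim) == 1.0
        assert esd_embedding_prob(lim.sigma_star / 2, lim) == 0.0
        assert esd_embedding_prob(2 * lim.sigma_star, lim) == 1.0


class TestVershyninBound:
    def test_degenerate_t_zero(self):
        (lo, hi), prob = vershynin_bound(r=0.5, n=100, k=20, d=5, t=0.0)
        assert lo == hi == 1.0
        assert prob == 0.0  # 1 - 2d clamps to zero for d >= 1

    def test_width_scaling_in_r(self):
        (lo1, hi1), _ = vershynin_bound(r=0.2, n=100, k=20, d=5, t=1.0)
        (lo2, hi2), _ = vershynin_bound(r=0.4, n=100, k=20, d=5, t=1.0)
        assert (hi2 - 1.0) == pytest.approx(np.sqrt(2) * (hi1 - 1.0), rel=1e-12)

    def test_flattest_leverage_width(self):
        n, k, d, t = 200, 50, 10, 1.3
        (lo, hi), _ = vershynin_bound(r=d / n, n=n, k=k, d=d, t=t)
        assert hi - 1.0 == pytest.approx(t * np.sqrt(d / k), rel=1e-12)

    def test_probability_becomes_informative(self):
        _, prob = vershynin_bound(r=0.1, n=1000, k=200, d=5, t=3.0, c=1.0)
        assert 0.0 < prob < 1.0

    def test_r_below_average_leverage_rejected(self):
        with pytest.raises(ValueError, match="d/n"):
            vershynin_bound(r=0.001, n=100, k=20, d=5, t=1.0)
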