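"""Closed-form Tracy-Widom and spectral-limit approximations.

For a Gaussian sketch of size k applied to a rank-d matrix, the sketched
Gram matrix W = U^T S^T S U is Wishart(k, I_d/k), and its extreme
eigenvalues obey Tracy-Widom fluctuation laws.  This module evaluates:

* the embedding probability approximation
      psi_hat(eps) = F1((eps + 1 - mu+) / sigma+),
  where (mu+, sigma+) are the O(d^(-2/3))-accurate centering and scaling
  constants of the largest Wishart eigenvalue;
* the convergence probability of the sketch-preconditioned least-squares
  iteration,
      gamma_hat = F1((nu - log(1/2)) / tau),
  from the logarithmic Tracy-Widom law of the smallest eigenvalue;
* the deterministic edge limits of the empirical spectral distribution of W
  for the subsampled Hadamard transform in the proportional regime
  d/n -> gamma, k/n -> xi, d/k -> alpha, and the induced step-function
  approximation to the embedding probability with threshold sigma*;
* Vershynin's tail bound for the uniform (row-subsampling) sketch in terms
  of the maximum leverage score.

Sign convention for the smallest-eigenvalue constants: the cube-root factor
(1/sqrt(k-1/2) - 1/sqrt(d-1/2)) is negative for k > d; the magnitude is
used so tau > 0 and the approximation increases to 1 as k/d grows, which is
the behaviour the exact probability Pr(lambda_min(W) > 1/2) exhibits (and
Monte-Carlo confirms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .tw_dist import tw1_cdf, tw1_quantile

__all__ = [
    "TWConstants",
    "SpectralLimits",
    "max_eig_constants",
    "min_eig_constants",
    "embedding_prob_tw",
    "embedding_quantile_tw",
    "convergence_prob_tw",
    "esd_limits",
    "esd_embedding_prob",
    "vershynin_bound",
    "convergence_prob_tw_cont",
    "convergence_half_prob_k",
]


@dataclass(frozen=True)
class TWConstants:
    """Centering/scaling constants of the extreme Wishart eigenvalues.

    ``mu_plus, sigma_plus`` center/scale the largest eigenvalue;
    ``mu_minus, sigma_minus`` the smallest (unnormalized, on the k*W scale),
    with ``tau = sigma_minus / mu_minus`` and
    ``nu = log(mu_minus) - log k - tau^2 / 8`` the constants of its
    logarithmic law.  The minus-family fields are None when k = d (degenerate
    smallest eigenvalue).
    """

    k: int
    d: int
    mu_plus: float
    sigma_plus: float
    mu_minus: float | None = None
    sigma_minus: float | None = None
    tau: float | None = None
    nu: float | None = None


def _check_kd(k: int, d: int, strict: bool) -> None:
    if d < 1:
        raise ValueError("d must be >= 1")
    if strict and k <= d:
        raise ValueError(f"need k > d, got k={k}, d={d}")
    if not strict and k < d:
        raise ValueError(f"need k >= d, got k={k}, d={d}")


def max_eig_constants(k: int, d: int) -> TWConstants:
    """Largest-eigenvalue constants mu+ and sigma+ (k >= d >= 1)."""
    _check_kd(k, d, strict=False)
    rk, rd = np.sqrt(k - 0.5), np.sqrt(d - 0.5)
    mu = (rk + rd) ** 2 / k
    # the cube-root factor multiplies (Johnstone/Ma form); Monte-Carlo on the
    # Wishart spectrum confirms the scale, which is O(k^{-2/3}) at fixed d/k
    sigma = ((rk + rd) / k) * (1.0 / rk + 1.0 / rd) ** (1.0 / 3.0)
    return TWConstants(k=k, d=d, mu_plus=float(mu), sigma_plus=float(sigma))


def min_eig_constants(k: int, d: int) -> TWConstants:
    """Smallest-eigenvalue constants (k > d >= 1), positive-tau convention."""
    _check_kd(k, d, strict=True)
    plus = max_eig_constants(k, d)
    rk, rd = np.sqrt(k - 0.5), np.sqrt(d - 0.5)
    mu = (rk - rd) ** 2
    sigma = (rk - rd) * abs(1.0 / rk - 1.0 / rd) ** (1.0 / 3.0)
    tau = sigma / mu
    nu = np.log(mu) - np.log(k) - tau**2 / 8.0
    return TWConstants(
        k=k, d=d, mu_plus=plus.mu_plus, sigma_plus=plus.sigma_plus,
        mu_minus=float(mu), sigma_minus=float(sigma), tau=float(tau), nu=float(nu),
    )


def embedding_prob_tw(epsilon, k: int, d: int):
    """Tracy-Widom approximation to the embedding probability.

    psi_hat = F1((epsilon + 1 - mu+) / sigma+); vectorized over epsilon.
    """
    eps = np.asarray(epsilon, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("epsilon must be positive")
    c = max_eig_constants(k, d)
    return tw1_cdf((eps + 1.0 - c.mu_plus) / c.sigma_plus)


def embedding_quantile_tw(p: float, k: int, d: int) -> float:
    """Distortion epsilon achieved with probability p (inverse of
    :func:`embedding_prob_tw` in epsilon)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly inside (0, 1)")
    c = max_eig_constants(k, d)
    eps = c.mu_plus - 1.0 + c.sigma_plus * tw1_quantile(p)
    if eps <= 0:
        # the TW surrogate assigns mass below zero distortion for tiny p;
        # find the probability actually attainable and report ~0+
        return float(np.finfo(float).tiny)
    return float(eps)


def convergence_prob_tw(k: int, d: int) -> float:
    """Tracy-Widom approximation to the convergence probability of the
    sketch-preconditioned iteration: gamma_hat = F1((nu - log(1/2)) / tau)."""
    c = min_eig_constants(k, d)
    return float(np.clip(tw1_cdf((c.nu - np.log(0.5)) / c.tau), 0.0, 1.0))


@dataclass(frozen=True)
class SpectralLimits:
    """Deterministic edge limits of the sketched-Gram spectrum in the
    proportional regime (Hadamard sketch, sampling without replacement)."""

    gamma: float
    xi: float
    alpha: float
    lambda_min_limit: float
    lambda_max_limit: float
    sigma_star: float


def esd_limits(gamma: float, xi: float, alpha: float) -> SpectralLimits:
    """Edge limits of the empirical spectral distribution of U^T S^T S U.

    lambda_min/max -> (sqrt(1 - gamma) -/+ sqrt((1 - xi) alpha))^2 and
    sigma* = max |1 - lambda_limit| is the induced step threshold on the
    distortion.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    if not gamma < xi < 1.0:
        raise ValueError("xi must lie in (gamma, 1)")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    root = np.sqrt((1.0 - xi) * alpha)
    lo = (np.sqrt(1.0 - gamma) - root) ** 2
    hi = (np.sqrt(1.0 - gamma) + root) ** 2
    sigma_star = max(abs(1.0 - lo), abs(1.0 - hi))
    return SpectralLimits(
        gamma=gamma, xi=xi, alpha=alpha,
        lambda_min_limit=float(lo), lambda_max_limit=float(hi),
        sigma_star=float(sigma_star),
    )


def esd_embedding_prob(epsilon, limits: SpectralLimits):
    """Step-function approximation: 1 if epsilon >= sigma*, else 0."""
    eps = np.asarray(epsilon, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("epsilon must be positive")
    out = (eps >= limits.sigma_star).astype(float)
    return float(out) if out.ndim == 0 else out


def vershynin_bound(r: float, n: int, k: int, d: int, t: float, c: float = 1.0):
    """Tail bound for the uniform sketch in terms of the leverage ceiling r.

    With probability at least 1 - 2 d exp(-c t^2) (clamped at 0), all
    singular values of S U lie in [1 - t sqrt(r n / k), 1 + t sqrt(r n / k)].
    The absolute constant c is not pinned down by the theory; the default 1
    makes the bound qualitative only.

    Returns ``((lo, hi), prob_lower_bound)``.
    """
    if not d / n <= r <= 1.0:
        raise ValueError(f"r must lie in [d/n, 1] = [{d / n}, 1], got {r}")
    if t < 0:
        raise ValueError("t must be >= 0")
    if c <= 0:
        raise ValueError("c must be > 0")
    half_width = t * np.sqrt(r * n / k)
    prob = max(0.0, 1.0 - 2.0 * d * np.exp(-c * t * t))
    return (1.0 - half_width, 1.0 + half_width), float(prob)


def convergence_prob_tw_cont(k: float, d: int) -> float:
    """Continuous-in-k relaxation of :func:`convergence_prob_tw`, for
    root-finding over sketch sizes."""
    rk, rd = np.sqrt(k - 0.5), np.sqrt(d - 0.5)
    mu = (rk - rd) ** 2
    sigma = (rk - rd) * abs(1.0 / rk - 1.0 / rd) ** (1.0 / 3.0)
    tau = sigma / mu
    nu = np.log(mu) - np.log(k) - tau**2 / 8.0
    return float(tw1_cdf((nu - np.log(0.5)) / tau))


def convergence_half_prob_k(d: int) -> int:
    """Smallest integer k at which the convergence approximation reaches 1/2
    for a given d (utility for choosing interesting sketch sizes)."""
    lo, hi = d + 1, 16 * d
    while convergence_prob_tw_cont(hi, d) < 0.5:
        hi *= 2
    if convergence_prob_tw_cont(lo, d) >= 0.5:
        return lo
    k_star = brentq(lambda x: convergence_prob_tw_cont(x, d) - 0.5, lo, hi)
    return int(np.ceil(k_star))
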