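"""Synthetic-data generators, leverage diagnostics and experiment drivers.

The generators emulate the simulation designs used to study sketching on
tall genomic/regression design matrices: rows drawn i.i.d. from N(0, Sigma)
with the AR(1) covariance Sigma_ij = rho^|i-j| (rho = 0.5 by default), a
linear-model response on top of such a design, and bootstrap row-resampling
to enlarge a matrix (which spreads leverage mass over duplicated rows).

The drivers restate the headline figures as desk-scale computations:

* :func:`experiment_embedding` -- empirical embedding-probability curve of a
  chosen sketch family against the Tracy-Widom approximation (and, in the
  proportional regime, the spectral-edge step approximation), summarized by
  the sup-distance between the curves;
* :func:`experiment_convergence` -- empirical convergence probability of the
  sketch-preconditioned least-squares iteration over a grid of sketch sizes,
  with binomial error bars, against the Tracy-Widom curve.

Every report embeds its full configuration and seed and is exactly
reproducible from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mc_oracle import (
    DistortionSample,
    empirical_embedding_prob,
    orthonormal_basis,
    simulate_gaussian_distortions,
    sketch_distortions,
)
from .precond_solver import empirical_convergence_prob
from .sketch_core import SketchFamily, SketchSpec, _as_rng
from .spectral_theory import (
    SpectralLimits,
    convergence_prob_tw,
    embedding_prob_tw,
    embedding_quantile_tw,
    esd_embedding_prob,
    esd_limits,
)

__all__ = [
    "LeverageProfile",
    "ExperimentReport",
    "gen_ar1_gaussian",
    "gen_regression",
    "gen_diluted_outliers",
    "leverage_scores",
    "bootstrap_enlarge",
    "default_epsilon_grid",
    "experiment_embedding",
    "experiment_convergence",
]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_ar1_gaussian(n: int, d: int, rho: float = 0.5, seed=0) -> np.ndarray:
    """n x d matrix with rows i.i.d. N(0, Sigma), Sigma_ij = rho^|i-j|.

    Generated via the stationary AR(1) recursion across columns, O(nd); no
    d x d factorization is formed.
    """
    if abs(rho) >= 1.0:
        raise ValueError("need |rho| < 1 for a stationary AR(1) covariance")
    rng = _as_rng(seed)
    E = rng.standard_normal((n, d))
    X = np.empty((n, d))
    X[:, 0] = E[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, d):
        X[:, j] = rho * X[:, j - 1] + scale * E[:, j]
    return X


def gen_regression(n: int, d: int, noise_sd: float = 1.0, rho: float = 0.5, seed=0):
    """AR(1) design plus linear response y = X beta* + noise.

    beta* has i.i.d. standard normal entries fixed by the seed.  Returns
    ``(X, y)`` of shapes (n, d) and (n,).
    """
    if n <= d:
        raise ValueError(f"need n > d, got n={n}, d={d}")
    rng = _as_rng(seed)
    X = gen_ar1_gaussian(n, d, rho=rho, seed=rng)
    beta_star = rng.standard_normal(d)
    y = X @ beta_star + noise_sd * rng.standard_normal(n)
    return X, y


def gen_diluted_outliers(
    n: int, d: int, n_outliers: int = 10, outlier_scale: float = 128.0, seed=0
) -> np.ndarray:
    """Standard-normal bulk plus a fixed set of heavy coordinate-aligned rows.

    Row j < n_outliers is ``outlier_scale * e_{j mod d}``; the remaining rows
    are i.i.d. N(0, I_d).  Because the outliers have fixed absolute magnitude
    while the bulk grows, their leverage scores decay like
    scale^2 / (scale^2 + n): the maximum leverage tends to zero as n grows
    but is substantial at small n.  This is the regime in which the
    universality of the structured sketches (their distortion law approaching
    the Gaussian/Wishart limit) is actually observable at desk scale -- an
    i.i.d. or AR(1) design is already indistinguishable from the limit at a
    few thousand rows.
    """
    if n_outliers >= n:
        raise ValueError("need n_outliers < n")
    rng = _as_rng(seed)
    A = rng.standard_normal((n, d))
    for j in range(n_outliers):
        A[j] = 0.0
        A[j, j % d] = outlier_scale
    return A


def bootstrap_enlarge(A: np.ndarray, factor: int, seed=0) -> np.ndarray:
    """Resample factor * n rows of A uniformly with replacement."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("A must be a non-empty 2-D matrix")
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    n = A.shape[0]
    rng = _as_rng(seed)
    rows = rng.integers(0, n, size=int(factor) * n)
    return A[rows]


# ---------------------------------------------------------------------------
# leverage diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeverageProfile:
    """Per-row leverage scores h_i = ||u_i||^2 of the left-singular basis.

    The scores sum to rank(A) and the maximum is at least d/n for a
    full-rank matrix; a maximum near 1 flags an observation whose removal
    would change the column space (the failure mode of row subsampling).
    """

    scores: np.ndarray
    max_score: float
    sum_score: float


def leverage_scores(A: np.ndarray) -> LeverageProfile:
    A = np.asarray(A, dtype=float)
    U, rank = orthonormal_basis(A, require_full_rank=False)
    scores = np.sum(U * U, axis=1)
    return LeverageProfile(
        scores=scores, max_score=float(scores.max()), sum_score=float(scores.sum())
    )


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentReport:
    """Reproducible summary of one experiment: configuration, the measured
    curve(s), the closed-form reference curve(s), and their sup-distance."""

    kind: str
    configuration: dict
    grid: np.ndarray
    empirical: np.ndarray
    theoretical: np.ndarray
    sup_distance: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "kind": self.kind,
            "configuration": self.configuration,
            "grid": np.asarray(self.grid).tolist(),
            "empirical": np.asarray(self.empirical).tolist(),
            "theoretical": np.asarray(self.theoretical).tolist(),
            "sup_distance": self.sup_distance,
        }
        for key, val in self.extras.items():
            out[key] = np.asarray(val).tolist() if isinstance(val, np.ndarray) else val
        return out


def default_epsilon_grid(k: int, d: int, num: int = 200) -> np.ndarray:
    """Epsilon grid spanning the 0.001-0.999 band of the Tracy-Widom
    embedding approximation for (k, d)."""
    lo = embedding_quantile_tw(0.001, k, d)
    hi = embedding_quantile_tw(0.999, k, d)
    return np.linspace(lo, hi, num)


def experiment_embedding(
    d: int,
    k: int,
    family: str | SketchFamily,
    B: int,
    n: int | None = None,
    epsilon_grid: Sequence[float] | None = None,
    seed: int = 0,
    rho: float = 0.5,
    A: np.ndarray | None = None,
    row_sampling: str = "with_replacement",
    include_esd_step: bool = False,
) -> ExperimentReport:
    """Empirical embedding-probability curve against the Tracy-Widom curve.

    For the Gaussian family the Wishart pivotality shortcut is used and no
    data matrix is needed.  Otherwise the sketch is applied to the
    left-singular basis of ``A`` (or of an AR(1) matrix generated with the
    given n, d, rho).  With ``include_esd_step`` the spectral-edge step
    approximation at (gamma, xi, alpha) = (d/n, k/n, d/k) is attached.
    """
    family = SketchFamily(family)
    grid = (
        np.asarray(epsilon_grid, dtype=float)
        if epsilon_grid is not None
        else default_epsilon_grid(k, d)
    )
    rng = _as_rng(seed)
    if family is SketchFamily.GAUSSIAN and A is None:
        sample = simulate_gaussian_distortions(k, d, B, seed=rng)
        n_used = None
    else:
        if A is None:
            if n is None:
                raise ValueError("n (or an explicit A) is required for this family")
            A = gen_ar1_gaussian(n, d, rho=rho, seed=rng)
        n_used = A.shape[0]
        spec = SketchSpec(family=family, k=k, row_sampling=row_sampling)
        sample = sketch_distortions(A, spec, B, seed=rng)
    empirical = empirical_embedding_prob(sample, grid)
    theoretical = embedding_prob_tw(grid, k, d)
    sup_dist = float(np.max(np.abs(empirical - theoretical)))
    extras: dict = {"draws": sample.draws}
    if include_esd_step:
        if n_used is None:
            raise ValueError("the spectral-edge step requires a finite n")
        limits = esd_limits(gamma=d / n_used, xi=k / n_used, alpha=d / k)
        extras["sigma_star"] = limits.sigma_star
        extras["esd_step"] = esd_embedding_prob(grid, limits)
    config = {
        "d": d, "k": k, "family": family.value, "B": B, "n": n_used,
        "rho": rho, "seed": seed, "row_sampling": row_sampling,
    }
    return ExperimentReport(
        kind="embedding", configuration=config, grid=grid,
        empirical=empirical, theoretical=theoretical,
        sup_distance=sup_dist, extras=extras,
    )


def experiment_convergence(
    n: int,
    d: int,
    k_grid: Sequence[int],
    family: str | SketchFamily,
    R: int,
    seed: int = 0,
    rho: float = 0.5,
    noise_sd: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> ExperimentReport:
    """Empirical convergence probability of the preconditioned iteration
    over a grid of sketch sizes, against the Tracy-Widom curve."""
    family = SketchFamily(family)
    k_grid = np.asarray(k_grid, dtype=int)
    rng = _as_rng(seed)
    X, y = gen_regression(n, d, noise_sd=noise_sd, rho=rho, seed=rng)
    estimates = np.empty(k_grid.size)
    ses = np.empty(k_grid.size)
    for i, k in enumerate(k_grid):
        estimates[i], ses[i] = empirical_convergence_prob(
            X, y, family.value, int(k), R, seed=rng, tol=tol, max_iter=max_iter
        )
    theoretical = np.array([convergence_prob_tw(int(k), d) for k in k_grid])
    sup_dist = float(np.max(np.abs(estimates - theoretical)))
    config = {
        "n": n, "d": d, "k_grid": k_grid.tolist(), "family": family.value,
        "R": R, "rho": rho, "noise_sd": noise_sd, "seed": seed,
        "tol": tol, "max_iter": max_iter,
    }
    return ExperimentReport(
        kind="convergence", configuration=config, grid=k_grid.astype(float),
        empirical=estimates, theoretical=theoretical, sup_distance=sup_dist,
        extras={"standard_errors": ses},
    )
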