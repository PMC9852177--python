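"""Distortion statistic and Monte-Carlo oracles for embedding probabilities.

A sketch S is an epsilon-subspace embedding for A exactly when the realized
distortion

    sigma_max(I_d - U^T S^T S U)
        = max(|1 - lambda_min(U^T S^T S U)|, |1 - lambda_max(U^T S^T S U)|)

is at most epsilon, where U is an orthonormal basis of col(A).  For the
Gaussian family the sketched Gram matrix U^T S^T S U is exactly
Wishart(k, I_d/k) whatever the data -- a pivotal quantity -- so its
distortion law can be simulated without ever forming an n-dimensional
object.  For the other families the oracle applies the sketch to U and
records the realized distortion draw by draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .sketch_core import SketchSpec, _as_rng, apply_sketch

__all__ = [
    "DistortionSample",
    "RankDeficiencyError",
    "distortion",
    "orthonormal_basis",
    "simulate_gaussian_distortions",
    "simulate_wishart_extreme_eigs",
    "sketch_distortions",
    "empirical_embedding_prob",
]

#: maximum allowed deviation of U^T U from the identity (max-norm)
ORTHONORMALITY_TOL = 1e-8


class RankDeficiencyError(ValueError):
    """Raised when a matrix required to have full column rank does not."""


@dataclass(frozen=True)
class DistortionSample:
    """B simulated distortion factors with their generating configuration."""

    draws: np.ndarray
    k: int
    d: int
    family: str
    seed: int | None = None

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        if draws.ndim != 1 or draws.size < 1:
            raise ValueError("draws must be a non-empty 1-D array")
        if np.any(draws < 0):
            raise ValueError("distortion draws must be non-negative")
        object.__setattr__(self, "draws", draws)

    @property
    def B(self) -> int:
        return self.draws.size


def distortion(U: np.ndarray, SU: np.ndarray) -> float:
    """Realized distortion of one sketch draw.

    ``U`` must have orthonormal columns (checked to 1e-8 in max norm); ``SU``
    is the sketched basis.  The statistic is evaluated through the symmetric
    d x d eigendecomposition of (SU)^T (SU) -- never an n x n object.
    """
    U = np.asarray(U, dtype=float)
    SU = np.asarray(SU, dtype=float)
    d = U.shape[1]
    gram_dev = np.abs(U.T @ U - np.eye(d)).max()
    if gram_dev > ORTHONORMALITY_TOL:
        raise ValueError(
            f"U is not orthonormal: max |U^T U - I| = {gram_dev:.3e} > {ORTHONORMALITY_TOL}"
        )
    return _distortion_of_gram(SU.T @ SU)


def _distortion_of_gram(M: np.ndarray) -> float:
    lam = np.linalg.eigvalsh(M)
    return float(max(abs(1.0 - lam[0]), abs(1.0 - lam[-1])))


def orthonormal_basis(A: np.ndarray, require_full_rank: bool = True):
    """Orthonormal basis of col(A) via thin SVD.

    Returns ``(U, rank)``.  Rank is decided with the standard relative
    tolerance max(n, d) * eps * sigma_max.  With ``require_full_rank`` (the
    default, needed by all theory operations) a rank < d raises
    :class:`RankDeficiencyError` naming the deficient count; otherwise U has
    ``rank`` columns.
    """
    A = np.asarray(A, dtype=float)
    n, d = A.shape
    if n < d:
        raise ValueError(f"need n >= d, got shape {A.shape}")
    U, s, _ = scipy.linalg.svd(A, full_matrices=False)
    tol = max(n, d) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if require_full_rank and rank < d:
        raise RankDeficiencyError(
            f"matrix has rank {rank} < {d} ({d - rank} deficient direction(s))"
        )
    return U[:, :rank], rank


def simulate_gaussian_distortions(k: int, d: int, B: int, seed=0) -> DistortionSample:
    """Simulate B distortion factors of the Gaussian sketch.

    Uses the pivotality shortcut: U^T S^T S U ~ Wishart(k, I_d/k) regardless
    of n or A, so each draw is the distortion of G^T G with G a k x d matrix
    of i.i.d. N(0, 1/k).  Batched over draws to keep the work in BLAS.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if k < 1 or d < 1:
        raise ValueError("k and d must be >= 1")
    rng = _as_rng(seed)
    draws = np.empty(B)
    # chunk so the (chunk, k, d) normal block stays small in memory
    chunk = max(1, min(B, int(2e7 // max(k * d, 1)) or 1))
    pos = 0
    while pos < B:
        m = min(chunk, B - pos)
        G = rng.standard_normal((m, k, d)) / np.sqrt(k)
        W = np.einsum("bki,bkj->bij", G, G, optimize=True)
        lam = np.linalg.eigvalsh(W)
        draws[pos : pos + m] = np.maximum(
            np.abs(1.0 - lam[:, 0]), np.abs(1.0 - lam[:, -1])
        )
        pos += m
    return DistortionSample(
        draws=draws, k=k, d=d, family="gaussian",
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_wishart_extreme_eigs(k: int, d: int, B: int, seed=0):
    """B draws of (lambda_min, lambda_max) of W ~ Wishart(k, I_d/k).

    The smallest eigenvalue drives the convergence probability of the
    sketch-preconditioned solver (the iteration converges iff
    lambda_min > 1/2), which the distortion statistic alone cannot recover.
    Returns two arrays of length B.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if k < 1 or d < 1:
        raise ValueError("k and d must be >= 1")
    rng = _as_rng(seed)
    lam_min = np.empty(B)
    lam_max = np.empty(B)
    chunk = max(1, min(B, int(2e7 // max(k * d, 1)) or 1))
    pos = 0
    while pos < B:
        m = min(chunk, B - pos)
        G = rng.standard_normal((m, k, d)) / np.sqrt(k)
        lam = np.linalg.eigvalsh(np.einsum("bki,bkj->bij", G, G, optimize=True))
        lam_min[pos : pos + m] = lam[:, 0]
        lam_max[pos : pos + m] = lam[:, -1]
        pos += m
    return lam_min, lam_max


def sketch_distortions(A: np.ndarray, spec: SketchSpec, B: int, seed=0) -> DistortionSample:
    """The oracle procedure: B independent sketches of the left-singular
    basis of ``A``, each reduced to its realized distortion factor.

    Works for any sketch family; requires rank(A) = d.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    U, _ = orthonormal_basis(A)
    rng = _as_rng(seed)
    draws = np.empty(B)
    for b in range(B):
        SU = apply_sketch(U, spec, seed=rng)
        draws[b] = _distortion_of_gram(SU.T @ SU)
    return DistortionSample(
        draws=draws, k=spec.k, d=U.shape[1], family=str(spec.family.value),
        seed=seed if isinstance(seed, int) else None,
    )


def empirical_embedding_prob(sample: DistortionSample, epsilon) -> float | np.ndarray:
    """Monte-Carlo embedding probability: fraction of draws <= epsilon.

    Right-continuous step function of epsilon; vectorized over epsilon.
    """
    eps = np.asarray(epsilon, dtype=float)
    scalar = eps.ndim == 0
    sorted_draws = np.sort(sample.draws)
    counts = np.searchsorted(sorted_draws, np.atleast_1d(eps), side="right")
    probs = counts / sample.B
    return float(probs[0]) if scalar else probs
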