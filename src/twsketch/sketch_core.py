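"""Data-oblivious random sketches of a tall data matrix.

A sketch compresses an n x d matrix ``A`` to a k x d surrogate ``S @ A``
through a random k x n matrix ``S`` whose law does not depend on the data.
Four families are provided:

``gaussian``
    i.i.d. N(0, 1/k) entries; O(ndk) to apply, exactly rotationally
    invariant (the sketched Gram matrix is Wishart(k, I_d/k) for any
    orthonormal input).
``hadamard``
    The subsampled randomized Hadamard transform S = Phi H D / sqrt(k):
    Rademacher sign flips D, a Sylvester-ordered Hadamard transform H of the
    zero-padded input, and row subsampling Phi (with replacement by default;
    without replacement is the variant used in spectral-limit analyses).
    Applied in O(n' d log n') via the fast Walsh-Hadamard transform, with
    n' the padded power-of-two size.
``clarkson_woodruff``
    CountSketch: every input row is assigned a uniform output row and a
    random sign, so S has one nonzero per column; applied in O(nd).
``uniform``
    Uniform row subsampling with replacement rescaled by sqrt(n/k).

Every family is exposed both as a matrix-free ``apply_*`` function (the
contract) and as a materialized dense operator (the test oracle).  Both draw
their random ingredients from one seeded generator in a fixed documented
order, so for the same ``(spec, seed, input)`` the apply function and the
dense product ``S @ A`` agree to floating-point round-off and the sketched
output is bit-reproducible.

RNG draw order per call (one ``numpy.random.Generator`` per call):
gaussian -- the k x n entries row-major; uniform -- the k row indices;
clarkson_woodruff -- n signs, then n output-row indices;
hadamard -- n' signs, then k sampled-row indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import scipy.linalg

__all__ = [
    "SketchFamily",
    "SketchSpec",
    "apply_gaussian",
    "apply_uniform",
    "apply_clarkson_woodruff",
    "apply_hadamard",
    "apply_sketch",
    "fwht",
    "materialize_sketch",
    "next_pow_two",
]


class SketchFamily(str, Enum):
    GAUSSIAN = "gaussian"
    HADAMARD = "hadamard"
    CLARKSON_WOODRUFF = "clarkson_woodruff"
    UNIFORM = "uniform"


@dataclass(frozen=True)
class SketchSpec:
    """Fully determines the law of a random sketch.

    Parameters
    ----------
    family : SketchFamily or str
    k : int
        Sketch size (number of output rows), >= 1.
    seed : int
        Seed for the per-call random generator.
    row_sampling : {"with_replacement", "without_replacement"}
        Hadamard only: how the row-subsampling matrix Phi picks the k rows.
    """

    family: SketchFamily
    k: int
    seed: int = 0
    row_sampling: str = "with_replacement"

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", SketchFamily(self.family))
        if self.k < 1:
            raise ValueError(f"sketch size k must be >= 1, got {self.k}")
        if self.row_sampling not in ("with_replacement", "without_replacement"):
            raise ValueError(f"unknown row_sampling {self.row_sampling!r}")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _validate_matrix(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got ndim={A.ndim}")
    if A.size == 0:
        raise ValueError("empty input matrix")
    if not np.all(np.isfinite(A)):
        raise ValueError("input matrix contains non-finite entries")
    return A


def next_pow_two(n: int) -> int:
    """Smallest power of two >= n."""
    return 1 << (int(n) - 1).bit_length()


def _rademacher(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 2, size=n).astype(float) * 2.0 - 1.0


# ---------------------------------------------------------------------------
# matrix-free apply functions
# ---------------------------------------------------------------------------

def apply_gaussian(A, k: int, seed=0) -> np.ndarray:
    """Gaussian sketch: S @ A with i.i.d. N(0, 1/k) entries in S."""
    A = _validate_matrix(A)
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = _as_rng(seed)
    S = rng.standard_normal((k, A.shape[0])) / np.sqrt(k)
    return S @ A


def apply_uniform(A, k: int, seed=0) -> np.ndarray:
    """Uniform sketch: sqrt(n/k)-rescaled row subsampling with replacement."""
    A = _validate_matrix(A)
    if k < 1:
        raise ValueError("k must be >= 1")
    n = A.shape[0]
    rng = _as_rng(seed)
    rows = rng.integers(0, n, size=k)
    return np.sqrt(n / k) * A[rows]


def apply_clarkson_woodruff(A, k: int, seed=0) -> np.ndarray:
    """CountSketch: each input row gets a random sign and output row.

    Streaming accumulation, O(nd); no dense S is materialized.
    """
    A = _validate_matrix(A)
    if k < 1:
        raise ValueError("k must be >= 1")
    n, d = A.shape
    rng = _as_rng(seed)
    signs = _rademacher(rng, n)
    rows = rng.integers(0, k, size=n)
    out = np.zeros((k, d))
    # accumulate signed rows into their target bucket; sort + reduceat keeps
    # this O(n log n) with vectorized adds rather than np.add.at's slow path
    order = np.argsort(rows, kind="stable")
    sorted_rows = rows[order]
    signed = signs[order, None] * A[order]
    boundaries = np.flatnonzero(np.concatenate([[True], np.diff(sorted_rows) > 0]))
    sums = np.add.reduceat(signed, boundaries, axis=0)
    out[sorted_rows[boundaries]] = sums
    return out


def fwht(x: np.ndarray) -> np.ndarray:
    """Fast Walsh-Hadamard transform H @ x (Sylvester ordering).

    ``x`` may be a vector or a matrix (transformed along axis 0); the length
    along axis 0 must be a power of two.  O(n log n) butterfly; returns a new
    array.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 1 or (n & (n - 1)) != 0:
        raise ValueError(f"FWHT length must be a power of two, got {n}")
    a = x.copy()
    shape_rest = a.shape[1:]
    h = 1
    while h < n:
        a = a.reshape(n // (2 * h), 2, h, *shape_rest)
        top = a[:, 0] + a[:, 1]
        bot = a[:, 0] - a[:, 1]
        a = np.stack([top, bot], axis=1)
        h *= 2
    return a.reshape(n, *shape_rest)


def _hadamard_ingredients(rng, n_pad: int, k: int, row_sampling: str):
    signs = _rademacher(rng, n_pad)
    if row_sampling == "with_replacement":
        rows = rng.integers(0, n_pad, size=k)
    else:
        if k > n_pad:
            raise ValueError(
                f"k={k} exceeds padded size {n_pad} for sampling without replacement"
            )
        rows = rng.choice(n_pad, size=k, replace=False)
    return signs, rows


def apply_hadamard(A, k: int, seed=0, row_sampling: str = "with_replacement") -> np.ndarray:
    """Subsampled randomized Hadamard transform, S = Phi H D / sqrt(k).

    The input is zero-padded to the next power of two n' so a Sylvester
    Hadamard matrix exists; computed via the column-wise fast transform in
    O(n' d log n').
    """
    A = _validate_matrix(A)
    if k < 1:
        raise ValueError("k must be >= 1")
    n, d = A.shape
    n_pad = next_pow_two(n)
    rng = _as_rng(seed)
    signs, rows = _hadamard_ingredients(rng, n_pad, k, row_sampling)
    padded = np.zeros((n_pad, d))
    padded[:n] = A
    padded *= signs[:, None]
    transformed = fwht(padded)
    return transformed[rows] / np.sqrt(k)


def apply_sketch(A, spec: SketchSpec, seed=None) -> np.ndarray:
    """Apply the sketch described by ``spec`` to ``A``.

    ``seed`` overrides ``spec.seed`` when given (an int or a Generator, so
    replicated draws can share one RNG stream).
    """
    s = spec.seed if seed is None else seed
    fam = spec.family
    if fam is SketchFamily.GAUSSIAN:
        return apply_gaussian(A, spec.k, s)
    if fam is SketchFamily.UNIFORM:
        return apply_uniform(A, spec.k, s)
    if fam is SketchFamily.CLARKSON_WOODRUFF:
        return apply_clarkson_woodruff(A, spec.k, s)
    if fam is SketchFamily.HADAMARD:
        return apply_hadamard(A, spec.k, s, spec.row_sampling)
    raise ValueError(f"unknown family {fam}")  # pragma: no cover


# ---------------------------------------------------------------------------
# dense operators (oracles for testing; small n only)
# ---------------------------------------------------------------------------

def materialize_sketch(spec: SketchSpec, n: int, seed=None) -> np.ndarray:
    """Dense k x n sketching matrix S drawing the same random ingredients as
    the corresponding apply function, so ``materialize_sketch(spec, n) @ A``
    equals ``apply_sketch(A, spec)`` to round-off.

    For the Hadamard family the returned operator is the k x n restriction of
    Phi H D / sqrt(k) to the original (unpadded) rows, which acts identically
    on the zero-padded input.  Intended as a test oracle; cost is O(kn).
    """
    rng = _as_rng(spec.seed if seed is None else seed)
    k = spec.k
    fam = spec.family
    if fam is SketchFamily.GAUSSIAN:
        return rng.standard_normal((k, n)) / np.sqrt(k)
    if fam is SketchFamily.UNIFORM:
        rows = rng.integers(0, n, size=k)
        S = np.zeros((k, n))
        S[np.arange(k), rows] = np.sqrt(n / k)
        return S
    if fam is SketchFamily.CLARKSON_WOODRUFF:
        signs = _rademacher(rng, n)
        rows = rng.integers(0, k, size=n)
        S = np.zeros((k, n))
        S[rows, np.arange(n)] = signs
        return S
    if fam is SketchFamily.HADAMARD:
        n_pad = next_pow_two(n)
        signs, rows = _hadamard_ingredients(rng, n_pad, k, spec.row_sampling)
        H = scipy.linalg.hadamard(n_pad).astype(float)
        S_full = (H[rows] * signs[None, :]) / np.sqrt(k)
        return S_full[:, :n]
    raise ValueError(f"unknown family {fam}")  # pragma: no cover
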