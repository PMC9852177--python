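"""Tracy-Widom distribution for the Gaussian orthogonal ensemble (beta = 1).

The centered and scaled extreme eigenvalues of large real Wishart matrices
converge in law to the Tracy-Widom distribution F1.  This module provides the
CDF and quantile function of F1 to absolute accuracy better than 1e-4, which
is what the closed-form embedding/convergence probability approximations in
:mod:`twsketch.spectral_theory` require.

The distribution is represented by a dense precomputed grid of (s, F1(s))
pairs shipped as a plain-text package asset, interpolated with a monotone
cubic (PCHIP) scheme.  The grid was generated once by an independent
high-precision oracle (``tools/gen_tw1_grid.py``, a Fredholm-determinant
evaluation of the GOE kernel); the library itself never needs any
special-function machinery at run time.  Outside the tabulated range
[-10, 7] the known leading-order tail asymptotics are used,

    log F1(s)       ~ -|s|^3 / 24            (s -> -inf),
    log(1 - F1(s))  ~ -(2/3) s^(3/2) - (3/2) log s   (s -> +inf),

with the additive constants fitted at the grid edges for continuity.  Both
tails are far beyond the 1e-6 probability range, so the fitted constants
only need to provide a smooth, monotone, clamped extension.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = ["TW1Table", "load_tw1_table", "tw1_cdf", "tw1_quantile", "tw1_grid_checksum"]

_GRID_ASSET = "tw1_cdf_grid.txt"


@dataclass(frozen=True)
class TW1Table:
    """Tabulated F1 CDF with tail-extrapolation parameters.

    Attributes
    ----------
    grid : ndarray
        Increasing abscissae s.
    cdf_values : ndarray
        F1(s) on the grid, strictly increasing within [0, 1].
    left_const, right_const : float
        Additive constants of the leading-order tail asymptotics, fitted at
        the grid edges.
    """

    grid: np.ndarray
    cdf_values: np.ndarray
    left_const: float
    right_const: float
    _interp: PchipInterpolator = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        g, c = self.grid, self.cdf_values
        if g.ndim != 1 or g.shape != c.shape:
            raise ValueError("grid and cdf_values must be 1-D of equal length")
        if np.any(np.diff(g) <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("grid and cdf_values must be strictly increasing")
        if c[0] >= 1e-6 or c[-1] <= 1 - 1e-6:
            raise ValueError("grid must cover the 1e-6 probability range")
        object.__setattr__(self, "_interp", PchipInterpolator(g, c, extrapolate=False))

    # -- CDF -------------------------------------------------------------
    def cdf(self, s):
        s = np.asarray(s, dtype=float)
        if np.any(np.isnan(s)):
            raise ValueError("NaN passed to the Tracy-Widom CDF")
        scalar = s.ndim == 0
        s = np.atleast_1d(s)
        out = np.empty_like(s)
        lo, hi = self.grid[0], self.grid[-1]
        inside = (s >= lo) & (s <= hi)
        out[inside] = self._interp(s[inside])
        left = s < lo
        out[left] = np.exp(-np.abs(s[left]) ** 3 / 24.0 + self.left_const)
        right = s > hi
        sr = s[right]
        out[right] = 1.0 - np.exp(
            -(2.0 / 3.0) * sr**1.5 - 1.5 * np.log(sr) + self.right_const
        )
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out

    # -- quantile --------------------------------------------------------
    def quantile(self, p):
        p = np.asarray(p, dtype=float)
        scalar = p.ndim == 0
        p = np.atleast_1d(p)
        if np.any(~((p > 0.0) & (p < 1.0))):
            raise ValueError("quantile requires p strictly inside (0, 1)")
        out = np.empty_like(p)
        c0, c1 = self.cdf_values[0], self.cdf_values[-1]
        for i, pi in enumerate(p):
            if pi <= c0:
                # invert the left-tail asymptotic directly
                out[i] = -((24.0 * (self.left_const - np.log(pi))) ** (1.0 / 3.0))
            elif pi >= c1:
                out[i] = brentq(lambda x: self.cdf(x) - pi, self.grid[-1], 200.0)
            else:
                j = np.searchsorted(self.cdf_values, pi)
                a, b = self.grid[max(j - 1, 0)], self.grid[min(j, len(self.grid) - 1)]
                out[i] = brentq(lambda x: self._interp(x) - pi, a, b, xtol=1e-12)
        return float(out[0]) if scalar else out


def _fit_tail_constants(grid: np.ndarray, cdf: np.ndarray) -> tuple[float, float]:
    left = np.log(cdf[0]) + np.abs(grid[0]) ** 3 / 24.0
    right = (
        np.log(1.0 - cdf[-1])
        + (2.0 / 3.0) * grid[-1] ** 1.5
        + 1.5 * np.log(grid[-1])
    )
    return float(left), float(right)


def _asset_bytes() -> bytes:
    return resources.files("twsketch").joinpath("data", _GRID_ASSET).read_bytes()


@lru_cache(maxsize=1)
def load_tw1_table() -> TW1Table:
    """Load the packaged F1 grid into a :class:`TW1Table` (cached)."""
    raw = np.loadtxt(_asset_bytes().decode().splitlines())
    grid, cdf = raw[:, 0], raw[:, 1]
    # trim any flat clamped region so the table is strictly increasing
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    grid, cdf = grid[keep], cdf[keep]
    left, right = _fit_tail_constants(grid, cdf)
    return TW1Table(grid=grid, cdf_values=cdf, left_const=left, right_const=right)


@lru_cache(maxsize=1)
def tw1_grid_checksum() -> str:
    """SHA-256 of the shipped grid asset, for provenance logging."""
    return hashlib.sha256(_asset_bytes()).hexdigest()


def tw1_cdf(s):
    """F1(s), the GOE Tracy-Widom CDF.  Accepts scalars or arrays."""
    return load_tw1_table().cdf(s)


def tw1_quantile(p):
    """Inverse of :func:`tw1_cdf` on p in (0, 1)."""
    return load_tw1_table().quantile(p)
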