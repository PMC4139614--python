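"""P-spline machinery for the nonlinear age effect.

A penalized B-spline (P-spline) smooth represents ``f(age)`` as ``B @ gamma``
where ``B`` is a cubic B-spline basis on an equidistant knot grid and the
coefficient vector carries a second-order random-walk (RW2) prior, i.e. a
Gaussian prior with precision ``K / tau2`` where ``K = D2' D2`` is built from
the second-difference operator.  ``K`` has rank ``m - 2``: constant and linear
coefficient sequences are unpenalized, so the smooth contains an unpenalized
linear trend and is identified against the intercept by empirical centering
over the observed ages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "make_knots", "bspline_design", "rw2_penalty", "center_smooth"]


def make_knots(xmin: float, xmax: float, n_inner: int, degree: int = 3) -> np.ndarray:
    """Open-uniform knot vector: equidistant inner knots, boundary knots
    replicated ``degree + 1`` times.  Yields ``n_inner + degree + 1`` basis
    functions."""
    if not xmax > xmin:
        raise ValueError("xmax must exceed xmin")
    if n_inner < 1:
        raise ValueError("need at least one inner knot")
    inner = np.linspace(xmin, xmax, n_inner + 2)[1:-1]
    return np.concatenate([np.repeat(xmin, degree + 1), inner, np.repeat(xmax, degree + 1)])


def rw2_penalty(m: int) -> np.ndarray:
    """RW2 penalty ``K = D2' D2`` for ``m`` coefficients (integer-valued,
    rank ``m - 2``, null space spanned by constant and linear sequences)."""
    if m < 3:
        raise ValueError("RW2 penalty needs at least 3 coefficients")
    D2 = np.diff(np.eye(m), n=2, axis=0)
    return D2.T @ D2


@dataclass(frozen=True)
class SplineBasis:
    """Cubic B-spline basis with RW2 penalty on a fixed support interval."""

    knots: np.ndarray
    degree: int = 3

    @classmethod
    def for_range(cls, xmin: float, xmax: float, n_basis: int = 20, degree: int = 3) -> "SplineBasis":
        """Basis with ``n_basis`` functions on ``[xmin, xmax]``."""
        return cls(make_knots(xmin, xmax, n_basis - degree - 1, degree), degree)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def xmin(self) -> float:
        return float(self.knots[0])

    @property
    def xmax(self) -> float:
        return float(self.knots[-1])

    def penalty(self) -> np.ndarray:
        return rw2_penalty(self.n_basis)

    def design(self, x: np.ndarray) -> np.ndarray:
        return bspline_design(np.asarray(x, dtype=float), self)


def bspline_design(x: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Evaluate the basis at ``x`` (dense matrix; rows sum to one).

    No extrapolation: values outside the knot span raise.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if np.any(x < basis.xmin) or np.any(x > basis.xmax):
        raise ValueError(
            f"x outside basis support [{basis.xmin}, {basis.xmax}]"
        )
    B = BSpline.design_matrix(x, basis.knots, basis.degree, extrapolate=False)
    return B.toarray()


def center_smooth(f_values: np.ndarray, weights: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Subtract the (weighted) mean of a smooth's fitted values.

    Returns the centered values and the extracted constant, which the caller
    absorbs into the intercept.
    """
    f = np.asarray(f_values, dtype=float)
    if weights is None:
        w = np.ones_like(f)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    tot = w.sum()
    if not tot > 0:
        raise ValueError("weights must have positive sum")
    const = float(f @ w / tot)
    return f - const, const
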