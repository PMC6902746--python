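"""Spline bases and penalized least-squares internals.

Two kinds of spline are used:

* P-splines: a cubic B-spline basis on uniformly spaced interior knots with
  a second-order difference penalty on the coefficients (Eilers-Marx).  With
  uniform knots the penalty's null space is exactly the straight lines in x,
  so linear signals pass through unshrunk at any penalty weight.  The weight
  is chosen by bisection so the trace of the smoother matrix (the effective
  degrees of freedom) hits a requested value.

* Natural cubic regression splines with a fixed, small basis (boundary knots
  at the data range, interior knots at quantiles) for the nested-model F
  tests, where the smooth must have exact integer degrees of freedom.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "bspline_knots",
    "bspline_design",
    "second_difference_penalty",
    "solve_penalized",
    "edf_for_lambda",
    "lambda_for_edf",
    "natural_spline_knots",
    "natural_spline_basis",
]


def bspline_knots(x_min: float, x_max: float, n_interior: int = 20,
                  degree: int = 3) -> np.ndarray:
    """Equidistant knot vector extending ``degree`` spacings beyond the range.

    Keeping every knot (including the exterior ones) on the same uniform grid
    makes the Greville abscissae equidistant, so coefficient vectors that are
    linear in index represent exactly the linear functions of x — the null
    space of the second-difference penalty.  Clamped (repeated) boundary
    knots would break that identity.
    """
    if not x_min < x_max:
        raise ValueError("x range is degenerate")
    h = (x_max - x_min) / (n_interior + 1)
    return x_min + h * np.arange(-degree, n_interior + 2 + degree)


def bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Dense B-spline design matrix; x must lie within the knot range."""
    x = np.asarray(x, dtype=float)
    lo, hi = knots[degree], knots[-degree - 1]
    if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
        raise ValueError("x outside the spline's support; extrapolation refused")
    x = np.clip(x, lo, hi)
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def second_difference_penalty(n_basis: int) -> np.ndarray:
    """Penalty matrix D'D for second-order coefficient differences."""
    d = np.diff(np.eye(n_basis), n=2, axis=0)
    return d.T @ d


def solve_penalized(B: np.ndarray, y: np.ndarray, P: np.ndarray,
                    lam: float) -> np.ndarray:
    """Coefficients of the penalized normal equations (B'B + lam P) b = B'y."""
    return np.linalg.solve(B.T @ B + lam * P, B.T @ y)


def edf_for_lambda(BtB: np.ndarray, P: np.ndarray, lam: float) -> float:
    """Effective degrees of freedom: trace of (B'B + lam P)^-1 B'B."""
    return float(np.trace(np.linalg.solve(BtB + lam * P, BtB)))


def lambda_for_edf(BtB: np.ndarray, P: np.ndarray, target_edf: float,
                   tol: float = 1e-3, max_iter: int = 200) -> float:
    """Penalty weight whose smoother trace equals ``target_edf``.

    Bisection on log10(lambda); the trace is strictly decreasing in lambda,
    from the basis size at lambda->0 down to the penalty null-space dimension
    (2 for second differences).
    """
    # bracket in units of the natural scale trace(B'B)/trace(P), expanding
    # upward only as far as needed (extreme lambda annihilates B'B in float64)
    scale = np.trace(BtB) / max(np.trace(P), 1.0)
    lo = np.log10(scale) - 10.0
    if edf_for_lambda(BtB, P, 10.0 ** lo) < target_edf - tol:
        raise ValueError(
            f"target edf {target_edf} exceeds the basis size even unpenalized"
        )
    hi = lo
    for _ in range(40):
        hi += 1.0
        if edf_for_lambda(BtB, P, 10.0 ** hi) < target_edf:
            break
    else:
        raise ValueError(
            f"target edf {target_edf} not attainable (penalty null space "
            "dimension is 2; ask for more)"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        edf = edf_for_lambda(BtB, P, 10.0 ** mid)
        if abs(edf - target_edf) <= tol:
            return 10.0 ** mid
        if edf > target_edf:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"edf bisection did not converge to {target_edf} in {max_iter} iterations"
    )


def natural_spline_knots(x: np.ndarray, df: int = 4) -> np.ndarray:
    """Knot sequence (boundary + interior at quantiles) for a df-column
    natural cubic spline basis; df=4 puts interior knots at the quartiles."""
    if df < 2:
        raise ValueError("natural spline needs df >= 2")
    x = np.asarray(x, dtype=float)
    probs = np.linspace(0, 1, df + 1)[1:-1]
    interior = np.quantile(x, probs)
    knots = np.r_[x.min(), interior, x.max()]
    if len(np.unique(knots)) != len(knots):
        raise ValueError("degenerate knots: too few distinct x values")
    return knots


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (without intercept), K knots -> K-1 columns.

    Truncated-power construction with linearity constraints beyond the
    boundary knots; first column is x itself.
    """
    x = np.asarray(x, dtype=float)
    K = len(knots)
    if K < 3:
        raise ValueError("need at least 3 knots")

    def d(j):  # scaled truncated cubics
        return (
            np.maximum(x - knots[j], 0) ** 3 - np.maximum(x - knots[K - 1], 0) ** 3
        ) / (knots[K - 1] - knots[j])

    cols = [x]
    dK2 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK2)
    return np.column_stack(cols)
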