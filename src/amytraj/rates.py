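"""Rate-of-accumulation curve: penalized-spline fit, group tests, integration.

The analytic core.  The annualized SUVR change of each participant is
modelled as a smooth function of their baseline SUVR,

    dA/dt_i = f(A0_i) + eps_i,

with f a cubic P-spline constrained to a fixed effective degrees of freedom
(4 by default, the trace of the smoother matrix).  The fitted rate curve can
then be integrated (classical Runge-Kutta) into a cumulative level-vs-time
trajectory, which is sigmoid when f is an inverted U.

Group comparisons use fixed-df natural cubic regression splines in nested
OLS models with analysis-of-deviance F tests:

* ``shape_difference_test`` — common curve vs group-specific curves;
* ``vertical_shift_test``  — additive group offset on a common penalized curve;
* ``linearity_test``       — straight line vs the 4-df spline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import splines

__all__ = [
    "RateCurveModel",
    "RateCurveResults",
    "TrajectoryCurve",
    "integrate_rate",
    "shape_difference_test",
    "vertical_shift_test",
    "linearity_test",
]


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

class RateCurveModel:
    """Penalized-spline regression of annualized SUVR change on baseline SUVR.

    Parameters
    ----------
    data
        Annualized-change table (one row per participant).
    group
        Group label to restrict to, or ``None`` for the pooled fit.
    x_col, y_col, group_col
        Column names; defaults match :func:`amytraj.annualize`.
    n_interior_knots, degree
        B-spline basis: uniform interior knots over the observed x range.

    ``fit(target_edf=4.0)`` chooses the penalty weight by bisection so the
    smoother-matrix trace equals ``target_edf``; ``fit(lam=...)`` freezes the
    weight instead.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        group: str | None = None,
        x_col: str = "baseline_suvr",
        y_col: str = "dsuvr_per_year",
        group_col: str = "group",
        n_interior_knots: int = 20,
        degree: int = 3,
    ):
        if group is not None:
            data = data[data[group_col] == group]
        sub = data[[x_col, y_col]].dropna()
        x = sub[x_col].to_numpy(dtype=float)
        y = sub[y_col].to_numpy(dtype=float)
        if len(x) < 10:
            raise ValueError(f"need at least 10 observations, got {len(x)}")
        if np.ptp(x) == 0:
            raise ValueError("baseline values are all identical")
        self.x, self.y = x, y
        self.group = group
        self.degree = degree
        self.knots = splines.bspline_knots(
            x.min(), x.max(), n_interior=n_interior_knots, degree=degree
        )
        self.B = splines.bspline_design(x, self.knots, degree)
        self.P = splines.second_difference_penalty(self.B.shape[1])

    def fit(self, target_edf: float = 4.0, lam: float | None = None
            ) -> "RateCurveResults":
        n = len(self.y)
        BtB = self.B.T @ self.B
        if lam is None:
            if not 1.0 < target_edf < n:
                raise ValueError("target_edf must lie in (1, n)")
            lam = splines.lambda_for_edf(BtB, self.P, target_edf)
        A = BtB + lam * self.P
        beta = np.linalg.solve(A, self.B.T @ self.y)
        edf = float(np.trace(np.linalg.solve(A, BtB)))
        fitted = self.B @ beta
        rss = float(np.sum((self.y - fitted) ** 2))
        scale = rss / max(n - edf, 1.0)
        Ainv_BtB = np.linalg.solve(A, BtB)
        cov = scale * (Ainv_BtB @ np.linalg.inv(A))
        cov = 0.5 * (cov + cov.T)
        return RateCurveResults(
            group=self.group,
            knots=self.knots,
            degree=self.degree,
            params=beta,
            lam=float(lam),
            edf=edf,
            scale=scale,
            cov_params=cov,
            x_range=(float(self.x.min()), float(self.x.max())),
            nobs=n,
            model=self,
        )


@dataclass
class RateCurveResults:
    """Fitted rate-vs-level curve with pointwise uncertainty."""

    group: str | None
    knots: np.ndarray
    degree: int
    params: np.ndarray
    lam: float
    edf: float
    scale: float  # residual variance, (SUVR/yr)^2
    cov_params: np.ndarray
    x_range: tuple[float, float]
    nobs: int
    model: RateCurveModel | None = field(default=None, repr=False)

    # -- evaluation --------------------------------------------------------
    def _design(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.x_range
        if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
            raise ValueError(
                f"prediction outside observed baseline range [{lo:.4g}, {hi:.4g}] "
                "is refused (no extrapolation)"
            )
        return splines.bspline_design(np.clip(x, lo, hi), self.knots, self.degree)

    def predict(self, x) -> np.ndarray:
        """Fitted rate (SUVR/yr) at baseline level x; no extrapolation."""
        return self._design(x) @ self.params

    def se(self, x) -> np.ndarray:
        B = self._design(x)
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, self.cov_params, B), 0.0))

    def conf_int(self, x, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise (1-alpha) confidence band for the rate curve."""
        pred, se = self.predict(x), self.se(x)
        z = stats.norm.ppf(1 - alpha / 2)
        return pred - z * se, pred + z * se

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.x)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    def argmax(self, num: int = 512) -> float:
        """Baseline SUVR at which the fitted rate curve peaks."""
        grid = np.linspace(*self.x_range, num)
        return float(grid[int(np.argmax(self.predict(grid)))])

    # -- integration ---------------------------------------------------------
    def integrate(
        self,
        start_level: float | None = None,
        t_max: float = 30.0,
        step: float = 0.05,
        epsilon: float = 1e-4,
    ) -> "TrajectoryCurve":
        """Cumulative SUVR-vs-time curve implied by the fitted rate.

        Integrates dA/dt = max(f(A), 0) by classical 4th-order Runge-Kutta
        from ``start_level`` (default: the 2.5th percentile of the observed
        baseline SUVR), stopping at ``t_max``, when the rate drops below
        ``epsilon`` (SUVR/yr), or when the level would leave the observed
        baseline range.  Negative fitted rates are clipped to zero here only:
        the cumulative curve is a level process.
        """
        if start_level is None:
            start_level = float(np.quantile(self.model.x, 0.025))
        lo, hi = self.x_range
        if not lo <= start_level <= hi:
            raise ValueError("start_level outside the fit's baseline range")
        return integrate_rate(
            lambda a: float(self.predict(a)[0]),
            start_level=start_level,
            t_max=t_max,
            step=step,
            epsilon=epsilon,
            level_max=hi,
        )

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Penalized-spline rate curve (SUVR change/yr vs baseline SUVR)",
            "=" * 62,
            f"group:            {self.group or 'pooled'}",
            f"n observations:   {self.nobs}",
            f"effective df:     {self.edf:.3f}",
            f"penalty weight:   {self.lam:.6g}",
            f"residual var:     {self.scale:.6g} (SUVR/yr)^2",
            f"baseline range:   [{self.x_range[0]:.3f}, {self.x_range[1]:.3f}]",
            f"peak rate:        {float(np.max(self.predict(np.linspace(*self.x_range, 512)))):.4f} SUVR/yr"
            f" at SUVR {self.argmax():.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, num: int = 200):
        """Rate curve with 95% band and the observations it was fitted to."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(*self.x_range, num)
        lo, hi = self.conf_int(grid)
        ax.fill_between(grid, lo, hi, alpha=0.25, label="95% CI")
        ax.plot(grid, self.predict(grid), label=f"fit ({self.group or 'pooled'})")
        if self.model is not None:
            ax.scatter(self.model.x, self.model.y, s=8, alpha=0.4, color="gray")
        ax.set_xlabel("baseline SUVR")
        ax.set_ylabel("SUVR change / yr")
        ax.legend()
        return ax

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "knots": self.knots.tolist(),
            "degree": self.degree,
            "params": self.params.tolist(),
            "lam": self.lam,
            "edf": self.edf,
            "scale": self.scale,
            "cov_params": self.cov_params.tolist(),
            "x_range": list(self.x_range),
            "nobs": self.nobs,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RateCurveResults":
        return cls(
            group=d["group"],
            knots=np.asarray(d["knots"], dtype=float),
            degree=int(d["degree"]),
            params=np.asarray(d["params"], dtype=float),
            lam=float(d["lam"]),
            edf=float(d["edf"]),
            scale=float(d["scale"]),
            cov_params=np.asarray(d["cov_params"], dtype=float),
            x_range=tuple(d["x_range"]),
            nobs=int(d["nobs"]),
        )

    @classmethod
    def from_json(cls, path: str) -> "RateCurveResults":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# trajectory integration
# --------------------------------------------------------------------------

@dataclass
class TrajectoryCurve:
    """Cumulative SUVR level as a function of time."""

    times: np.ndarray
    levels: np.ndarray
    start_level: float
    stop_reason: str  # reached_t_max | rate_below_epsilon | left_data_range

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_years": self.times, "suvr": self.levels})


def integrate_rate(
    rate_fn,
    start_level: float,
    t_max: float = 30.0,
    step: float = 0.05,
    epsilon: float = 1e-4,
    level_max: float = np.inf,
) -> TrajectoryCurve:
    """RK4 integration of dA/dt = max(rate_fn(A), 0) on a fixed time step.

    Stops early when the (clipped) rate falls below ``epsilon`` or a step
    would carry the level beyond ``level_max`` (the fit's data range).
    """
    if step <= 0:
        raise ValueError("step must be > 0")

    def g(a: float) -> float:
        if a > level_max:
            raise _LeftRange
        return max(rate_fn(a), 0.0)

    times = [0.0]
    levels = [float(start_level)]
    a, t = float(start_level), 0.0
    stop = None
    while t < t_max - 1e-12:
        try:
            k1 = g(a)
            if k1 < epsilon:
                stop = "rate_below_epsilon"
                break
            h = min(step, t_max - t)
            k2 = g(a + 0.5 * h * k1)
            k3 = g(a + 0.5 * h * k2)
            k4 = g(a + h * k3)
        except _LeftRange:
            stop = "left_data_range"
            break
        a_next = a + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if a_next > level_max:
            stop = "left_data_range"
            break
        a, t = a_next, t + h
        times.append(t)
        levels.append(a)
    return TrajectoryCurve(
        times=np.asarray(times),
        levels=np.asarray(levels),
        start_level=float(start_level),
        stop_reason=stop or "reached_t_max",
    )


class _LeftRange(Exception):
    pass


# --------------------------------------------------------------------------
# nested-model group tests
# --------------------------------------------------------------------------

@dataclass
class FTestResult:
    statistic: float
    pvalue: float
    df_num: float
    df_den: float


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2))


def _prepare_groups(
    data: pd.DataFrame, x_col: str, y_col: str, group_col: str
):
    sub = data[[x_col, y_col, group_col]].dropna()
    labels = sorted(sub[group_col].unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, found {labels}")
    for lab in labels:
        g = sub[sub[group_col] == lab]
        if len(g) < 10:
            raise ValueError(f"group {lab!r} has fewer than 10 observations")
        if g[x_col].nunique() < 5:
            raise ValueError(f"group {lab!r} has fewer than 5 distinct x values")
    x = sub[x_col].to_numpy(dtype=float)
    y = sub[y_col].to_numpy(dtype=float)
    # indicator is 1 for the 'case' group when present, else for the 2nd label
    case_label = "case" if "case" in labels else labels[1]
    g = (sub[group_col] == case_label).to_numpy(dtype=float)
    return x, y, g, case_label


def shape_difference_test(
    data: pd.DataFrame,
    x_col: str = "baseline_suvr",
    y_col: str = "dsuvr_per_year",
    group_col: str = "group",
    spline_df: int = 4,
) -> FTestResult:
    """Do the two groups share one rate-vs-level curve?

    Analysis-of-deviance F test of a common fixed 4-df natural cubic
    regression spline (M0) against group-specific splines plus a group
    intercept (M1); knots are placed on the pooled x.
    """
    x, y, g, _ = _prepare_groups(data, x_col, y_col, group_col)
    knots = splines.natural_spline_knots(x, df=spline_df)
    N = splines.natural_spline_basis(x, knots)
    one = np.ones_like(x)
    X0 = np.column_stack([one, N])
    X1 = np.column_stack([one, g, N, N * g[:, None]])
    return _nested_f(_ols_rss(X0, y), _ols_rss(X1, y),
                     df0=X0.shape[1], df1=X1.shape[1], n=len(y))


def linearity_test(
    data: pd.DataFrame,
    x_col: str = "baseline_suvr",
    y_col: str = "dsuvr_per_year",
    spline_df: int = 4,
) -> FTestResult:
    """Is the rate-vs-level association linear?

    F test of the straight line against the fixed 4-df regression spline.
    """
    if spline_df <= 1:
        raise ValueError("spline_df must exceed the line's 1 df (degenerate nesting)")
    sub = data[[x_col, y_col]].dropna()
    x = sub[x_col].to_numpy(dtype=float)
    y = sub[y_col].to_numpy(dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    knots = splines.natural_spline_knots(x, df=spline_df)
    N = splines.natural_spline_basis(x, knots)
    one = np.ones_like(x)
    X0 = np.column_stack([one, x])
    X1 = np.column_stack([one, N])
    return _nested_f(_ols_rss(X0, y), _ols_rss(X1, y),
                     df0=2, df1=X1.shape[1], n=len(y))


def _nested_f(rss0: float, rss1: float, df0: int, df1: int, n: int) -> FTestResult:
    ddf = df1 - df0
    if ddf <= 0:
        raise ValueError("models are not strictly nested (zero df difference)")
    df_den = n - df1
    if df_den <= 0:
        raise ValueError("too few observations for the larger model")
    num = max(rss0 - rss1, 0.0) / ddf
    den = rss1 / df_den
    if den == 0.0:
        f = 0.0 if num == 0.0 else np.inf
    else:
        f = num / den
    p = float(stats.f.sf(f, ddf, df_den)) if np.isfinite(f) else 0.0
    return FTestResult(statistic=float(f), pvalue=p, df_num=ddf, df_den=df_den)


@dataclass
class ShiftTestResult:
    coefficient: float  # SUVR/yr; positive = cases accumulate faster
    se: float
    pvalue: float


def vertical_shift_test(
    data: pd.DataFrame,
    x_col: str = "baseline_suvr",
    y_col: str = "dsuvr_per_year",
    group_col: str = "group",
    target_edf: float = 4.0,
    n_interior_knots: int = 20,
    degree: int = 3,
) -> ShiftTestResult:
    """Additive group offset on a common penalized rate curve.

    Fits y = f(x) + delta * 1[case] with f a P-spline whose penalty weight is
    calibrated (on the smooth term alone) to ``target_edf``; the indicator is
    unpenalized.  Returns the offset in SUVR/yr, its SE and two-sided p value
    (t reference with n - total edf denominator df).
    """
    x, y, g, _ = _prepare_groups(data, x_col, y_col, group_col)
    knots = splines.bspline_knots(x.min(), x.max(), n_interior_knots, degree)
    B = splines.bspline_design(x, knots, degree)
    P = splines.second_difference_penalty(B.shape[1])
    lam = splines.lambda_for_edf(B.T @ B, P, target_edf)

    X = np.column_stack([B, g])
    Pfull = np.zeros((X.shape[1], X.shape[1]))
    Pfull[: B.shape[1], : B.shape[1]] = P
    XtX = X.T @ X
    A = XtX + lam * Pfull
    beta = np.linalg.solve(A, X.T @ y)
    edf_total = float(np.trace(np.linalg.solve(A, XtX)))
    rss = float(np.sum((y - X @ beta) ** 2))
    scale = rss / max(len(y) - edf_total, 1.0)
    Ainv = np.linalg.inv(A)
    cov = scale * (Ainv @ XtX @ Ainv)
    coef = float(beta[-1])
    se = float(np.sqrt(max(cov[-1, -1], 0.0)))
    if se == 0.0:
        p = 1.0 if coef == 0.0 else 0.0
    else:
        p = float(2 * stats.t.sf(abs(coef / se), max(len(y) - edf_total, 1.0)))
    return ShiftTestResult(coefficient=coef, se=se, pvalue=p)
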