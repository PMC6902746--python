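"""Sample sizes for slope-reduction trials via mixed models + jackknife.

A random-intercept/random-slope linear mixed model

    y_ij = (b0 + u0_i) + (b1 + u1_i) t_ij + e_ij,
    (u0, u1) ~ N(0, G) unstructured,  e ~ N(0, s2),

fitted by REML, supplies the mean annual slope b1 and the variance
components.  For a two-arm trial powered to detect a fractional reduction
``delta`` of that slope with a one-sided z test, the per-arm size is

    n = 2 (z_{1-alpha} + z_{power})^2 (var_slope + s2 / Sxx) / (delta b1)^2,

with Sxx the visit-time sum of squares of the design schedule.  Leave-one-
subject-out jackknife resampling turns this into a mean with an asymptotic
confidence interval, as tabulated per outcome x follow-up x reduction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import GeneratorConfig
from .simulate import generate_cohort

__all__ = [
    "LMMFit",
    "TrialDesign",
    "SampleSizeEstimate",
    "fit_lmm",
    "required_n",
    "jackknife_sample_size",
    "sample_size_table",
    "schedule_for_duration",
]

logger = logging.getLogger(__name__)


@dataclass
class LMMFit:
    intercept: float
    slope: float
    var_intercept: float
    var_slope: float
    cov_int_slope: float
    var_residual: float
    n_subjects: int
    converged: bool
    loglike: float


@dataclass
class TrialDesign:
    """One cell of the hypothetical-trial grid.

    ``visit_times`` are assessment times in years including baseline 0;
    ``reduction`` is the fraction of the mean slope the treatment removes.
    One-sided alpha and power follow the published assumptions (0.05, 0.80).
    """

    reduction: float
    visit_times: list[float] = field(default_factory=lambda: [0.0, 1.0, 1.5, 2.0])
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5) (one-sided)")
        if not 0.5 < self.power < 1:
            raise ValueError("power must lie in (0.5, 1)")
        if not 0 < self.reduction <= 1:
            raise ValueError("reduction must lie in (0, 1]")
        vt = list(self.visit_times)
        if len(vt) < 2 or vt[0] != 0 or any(b <= a for a, b in zip(vt, vt[1:])):
            raise ValueError("visit_times must be >= 2 times, strictly increasing from 0")


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    subject_col: str = "participant_id",
    time_col: str = "time_years",
) -> LMMFit:
    """REML fit of the random-intercept/random-slope model for one outcome."""
    sub = data[[subject_col, time_col, outcome]].dropna()
    n_visits = sub.groupby(subject_col).size()
    keep = n_visits[n_visits >= 2].index
    sub = sub[sub[subject_col].isin(keep)]
    m = len(keep)
    if m < 4:
        raise ValueError(f"need >= 4 subjects with >= 2 visits, got {m}")
    y = sub[outcome].to_numpy(dtype=float)
    t = sub[time_col].to_numpy(dtype=float)

    # degenerate noiseless data: every observation on one common line
    X = np.column_stack([np.ones_like(t), t])
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta_ols) ** 2))
    if rss < 1e-12 * max(1.0, float(np.sum(y**2))):
        return LMMFit(
            intercept=float(beta_ols[0]), slope=float(beta_ols[1]),
            var_intercept=0.0, var_slope=0.0, cov_int_slope=0.0,
            var_residual=0.0, n_subjects=m, converged=True, loglike=np.inf,
        )

    exog = sm.add_constant(pd.DataFrame({"time": t}))
    model = sm.MixedLM(
        y, exog, groups=sub[subject_col].to_numpy(), exog_re=exog
    )
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # near-boundary variance components trip single optimizers; retry
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=True, method=method, maxiter=500)
            except Exception:  # noqa: BLE001 - singular fits happen on resamples
                continue
            if res is None or (cand.converged and not res.converged):
                res = cand
            if res.converged:
                break
    if res is None:
        return LMMFit(*np.full(6, np.nan), n_subjects=m, converged=False,
                      loglike=np.nan)
    cov_re = np.asarray(res.cov_re)
    return LMMFit(
        intercept=float(res.fe_params.iloc[0]),
        slope=float(res.fe_params.iloc[1]),
        var_intercept=float(cov_re[0, 0]),
        var_slope=float(cov_re[1, 1]),
        cov_int_slope=float(cov_re[0, 1]),
        var_residual=float(res.scale),
        n_subjects=m,
        converged=bool(res.converged),
        loglike=float(res.llf),
    )


def required_n(fit: LMMFit, design: TrialDesign, force: bool = False) -> float:
    """Unrounded per-arm sample size for the slope-reduction trial.

    The tabulated integer is the ceiling of this value; keeping it unrounded
    preserves exact 1/reduction^2 scaling across cells.
    """
    if not fit.converged and not force:
        raise ValueError("mixed model did not converge; pass force=True to override")
    if fit.slope == 0 or not np.isfinite(fit.slope):
        raise ValueError("zero mean slope: the effect is undetectable")
    times = np.asarray(design.visit_times, dtype=float)
    sxx = float(np.sum((times - times.mean()) ** 2))
    if sxx == 0:
        raise ValueError("degenerate visit schedule (zero time spread)")
    v = fit.var_slope + fit.var_residual / sxx
    z = stats.norm.ppf(1 - design.alpha) + stats.norm.ppf(design.power)
    return 2.0 * z**2 * v / (design.reduction * fit.slope) ** 2


@dataclass
class SampleSizeEstimate:
    outcome: str
    follow_up_months: int
    reduction_pct: float
    n_per_arm_mean: float
    ci_low: float
    ci_high: float
    n_jackknife_replicates: int

    @property
    def n_per_arm(self) -> int:
        """Display value: ceiling of the jackknife mean."""
        return int(np.ceil(self.n_per_arm_mean))


def _jackknife_fits(
    data: pd.DataFrame,
    outcome: str,
    subject_col: str,
    time_col: str,
    max_dropped_fraction: float,
) -> list[LMMFit]:
    """Leave-one-subject-out mixed-model refits (non-converged ones dropped)."""
    subjects = data[subject_col].unique()
    m = len(subjects)
    if m < 6:
        raise ValueError("jackknife needs >= 6 subjects")
    fits = []
    dropped = 0
    for s in subjects:
        fit = fit_lmm(
            data[data[subject_col] != s], outcome,
            subject_col=subject_col, time_col=time_col,
        )
        if not fit.converged or not np.isfinite(fit.slope) or fit.slope == 0:
            dropped += 1
            continue
        fits.append(fit)
    if dropped > max_dropped_fraction * m:
        raise RuntimeError(
            f"{dropped}/{m} jackknife replicates failed to converge for "
            f"{outcome!r}"
        )
    if dropped:
        logger.warning("dropped %d/%d non-converged jackknife replicates (%s)",
                       dropped, m, outcome)
    return fits


def _aggregate(reps: np.ndarray, outcome: str, months: int,
               reduction: float) -> SampleSizeEstimate:
    k = len(reps)
    mean = float(reps.mean())
    se = float(np.sqrt((k - 1) / k * np.sum((reps - mean) ** 2)))
    return SampleSizeEstimate(
        outcome=outcome,
        follow_up_months=months,
        reduction_pct=reduction * 100.0,
        n_per_arm_mean=mean,
        # asymptotic CI, truncated at 0: a per-arm size cannot be negative
        ci_low=max(mean - 1.96 * se, 0.0),
        ci_high=mean + 1.96 * se,
        n_jackknife_replicates=k,
    )


def jackknife_sample_size(
    data: pd.DataFrame,
    design: TrialDesign,
    outcome: str,
    subject_col: str = "participant_id",
    time_col: str = "time_years",
    follow_up_months: int | None = None,
    max_dropped_fraction: float = 0.2,
) -> SampleSizeEstimate:
    """Leave-one-subject-out jackknife of the per-arm sample size.

    Refits the mixed model on each leave-one-out sample, recomputes
    ``required_n`` and reports the replicate mean with the asymptotic CI
    mean +- 1.96 * SE, SE^2 = (m-1)/m * sum (n_i - nbar)^2.  Non-converged
    replicates are dropped (error if more than ``max_dropped_fraction``).
    """
    fits = _jackknife_fits(data, outcome, subject_col, time_col,
                           max_dropped_fraction)
    reps = np.asarray([required_n(f, design) for f in fits])
    months = follow_up_months if follow_up_months is not None else int(
        round(design.visit_times[-1] * 12)
    )
    return _aggregate(reps, outcome, months, design.reduction)


def schedule_for_duration(duration_months: int,
                          schedule_months: list[int] | None = None) -> list[float]:
    """Visit times (years) for one trial duration.

    Assessments accumulate: a 24-month trial reads at 0, 12, 18 and 24
    months.  ``schedule_months`` is the master reading schedule.
    """
    master = schedule_months or [0, 12, 18, 24, 36]
    times = [t for t in master if t <= duration_months]
    if duration_months not in times:
        times.append(duration_months)
    if len(times) < 2:
        raise ValueError(f"duration {duration_months} mo admits fewer than 2 visits")
    return [t / 12.0 for t in sorted(times)]


def sample_size_table(
    config: GeneratorConfig,
    outcomes: list[str] = ("suvr", "cdr_sob", "drs", "mmse"),
    follow_ups_months: list[int] = (12, 18, 24, 36),
    reductions: list[float] = (0.25, 0.50),
    n_subjects: int | None = None,
    alpha: float = 0.05,
    power: float = 0.80,
    schedule_months: list[int] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full sample-size grid for the hypothetical patient-arm trial.

    Simulates the case arm once on the master reading schedule from the
    generator's latent accumulation model and estimates variance components
    per outcome on it (leave-one-subject-out).  Each follow-up duration then
    enters only through its trial schedule's time spread Sxx in the closed
    form, so within every jackknife replicate the 25%/50% pair differs by a
    factor of exactly 4 and the per-arm size is nonincreasing in duration.
    """
    master = sorted(set(schedule_months or [0, 12, 18, 24, 36]) | {0}
                    | set(follow_ups_months))
    n_sub = n_subjects if n_subjects is not None else config.n_cases
    import dataclasses as _dc

    sim_cfg = _dc.replace(
        config,
        n_cases=n_sub,
        control_pool_size=0,
        seed=config.seed if seed is None else seed,
    )
    _, visits = generate_cohort(sim_cfg, visit_times=[t / 12.0 for t in master])

    rows = []
    for outcome in outcomes:
        fits = _jackknife_fits(
            visits, outcome, "participant_id", "time_years",
            max_dropped_fraction=0.2,
        )
        for dur in follow_ups_months:
            times = schedule_for_duration(dur, master)
            for red in reductions:
                design = TrialDesign(
                    reduction=red, visit_times=times, alpha=alpha, power=power
                )
                reps = np.asarray([required_n(f, design) for f in fits])
                est = _aggregate(reps, outcome, dur, red)
                rows.append(
                    {
                        "outcome": outcome,
                        "follow_up_months": dur,
                        "reduction_pct": est.reduction_pct,
                        "n_mean": est.n_per_arm_mean,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "n_per_arm": est.n_per_arm,
                        "n_replicates_used": est.n_jackknife_replicates,
                    }
                )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["outcome", "follow_up_months", "reduction_pct"], kind="stable"
    ).reset_index(drop=True)
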