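"""Matched case-control cohort simulator.

Amyloid load follows a bounded logistic law: the level A(t) solves

    dA/dt = r (A - L)(U - A),    L < A < U,

so the rate of accumulation, plotted against the current level, is an
inverted U peaking at (L+U)/2, and the level itself traces a sigmoid in
time.  Observed SUVR adds Gaussian measurement noise.  Clinical scores
change linearly in time with per-participant slopes coupled to latent
baseline SUVR and latent annualized SUVR change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    CLINICAL_MEASURES,
    SCORE_BOUNDS,
    VISIT_COLUMNS,
    GeneratorConfig,
)

__all__ = ["logistic_level", "accumulation_rate", "generate_cohort"]


def accumulation_rate(level, r=0.112, L=1.1, U=2.5):
    """Instantaneous accumulation rate r (A - L)(U - A) at the given level.

    The inverted-U rate law underlying :func:`logistic_level`; peaks at
    (L + U)/2 with value r (U - L)^2 / 4.
    """
    level = np.asarray(level, dtype=float)
    return r * (level - L) * (U - level)


def logistic_level(a0, r, L, U, t):
    """Amyloid level after ``t`` years starting from level ``a0``.

    Closed-form solution of dA/dt = r (A - L)(U - A):

        A(t) = L + (U - L) x(t),
        x(t) = x0 / (x0 + (1 - x0) exp(-r (U - L) t)),  x0 = (a0 - L)/(U - L).

    Vectorized in ``a0`` and ``t``.  Raises for a0 outside (L, U) or t < 0.
    """
    a0 = np.asarray(a0, dtype=float)
    t = np.asarray(t, dtype=float)
    if not L < U:
        raise ValueError("requires L < U")
    if np.any(a0 <= L) or np.any(a0 >= U):
        raise ValueError("starting level must lie strictly inside (L, U)")
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if r < 0:
        raise ValueError("growth rate must be nonnegative")
    x0 = (a0 - L) / (U - L)
    x = x0 / (x0 + (1.0 - x0) * np.exp(-r * (U - L) * t))
    out = L + (U - L) * x
    if out.ndim == 0:
        return float(out)
    return out


def _exact_flags(n: int, fraction: float) -> np.ndarray:
    """Boolean vector of length n with round(n*fraction) True entries,
    evenly spread, so integral compositions are reproduced exactly."""
    k = int(round(n * fraction))
    flags = np.zeros(n, dtype=bool)
    if k > 0:
        pos = np.floor(np.arange(k) * n / k).astype(int)
        flags[pos] = True
    return flags


def _truncated_normal(rng, mean, sd, low, high, size):
    if sd == 0:
        vals = np.full(size, float(mean))
        if np.any(vals <= low) or np.any(vals >= high):
            raise ValueError("degenerate draw outside truncation bounds")
        return vals
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _make_group(rng, cfg: GeneratorConfig, group: str, n: int, prefix: str):
    mu, sd = cfg.baseline_level_distribution[group]
    eps = 1e-9 * (cfg.ceiling_U - cfg.floor_L)
    return pd.DataFrame(
        {
            "id": [f"{prefix}{i:04d}" for i in range(n)],
            "group": group,
            "age": rng.normal(cfg.age_mean, cfg.age_sd, size=n),
            "sex": np.where(_exact_flags(n, cfg.male_fraction), "M", "F"),
            "apoe4": np.where(
                _exact_flags(n, cfg.apoe4_fraction), "carrier", "noncarrier"
            ),
            "latent_baseline_level": _truncated_normal(
                rng, mu, sd, cfg.floor_L + eps, cfg.ceiling_U - eps, n
            ),
            "match_block": pd.array([None] * n, dtype="object"),
        }
    )


def generate_cohort(
    config: GeneratorConfig, visit_times: list[float] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate participants and their visit-level observations.

    Parameters
    ----------
    config
        Generator parameters; ``config.seed`` makes the output deterministic.
    visit_times
        If ``None`` (observational mode) each participant gets a baseline
        visit at t=0 plus one follow-up at a group-specific random interval
        (truncated normal, minimum 0.5 y).  Otherwise every participant is
        observed at exactly these times (trial mode), which must start at 0.

    Returns
    -------
    (participants, visits)
        ``participants`` has one row per person (id, group, age, sex, apoe4,
        latent_baseline_level, match_block); ``visits`` one row per visit in
        the canonical column order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = []
    if config.n_cases > 0:
        groups.append(_make_group(rng, config, "case", config.n_cases, "case_"))
    if config.control_pool_size > 0:
        groups.append(
            _make_group(rng, config, "control", config.control_pool_size, "ctrl_")
        )
    if not groups:
        participants = pd.DataFrame(
            columns=[
                "id", "group", "age", "sex", "apoe4",
                "latent_baseline_level", "match_block",
            ]
        )
        visits = pd.DataFrame(columns=list(VISIT_COLUMNS))
        return participants, visits
    participants = pd.concat(groups, ignore_index=True)
    n = len(participants)

    # follow-up schedule
    if visit_times is None:
        intervals = np.empty(n)
        for grp in ("case", "control"):
            mask = (participants["group"] == grp).to_numpy()
            if mask.any():
                intervals[mask] = _truncated_normal(
                    rng,
                    config.interval_mean[grp],
                    config.interval_sd[grp],
                    0.5,
                    np.inf,
                    int(mask.sum()),
                )
        times = np.column_stack([np.zeros(n), intervals])  # (n, 2)
    else:
        vt = np.asarray(visit_times, dtype=float)
        if vt.size < 2 or vt[0] != 0 or np.any(np.diff(vt) <= 0):
            raise ValueError("visit_times must start at 0 and strictly increase")
        times = np.tile(vt, (n, 1))

    a0 = participants["latent_baseline_level"].to_numpy()
    latent = logistic_level(
        a0[:, None], config.growth_r, config.floor_L, config.ceiling_U, times
    )
    suvr_obs = latent + rng.normal(0.0, config.suvr_noise_sd, size=latent.shape) \
        if config.suvr_noise_sd > 0 else latent.copy()

    # latent annualized SUVR change over each participant's full window
    t_last = times[:, -1]
    latent_dsuvr = (latent[:, -1] - a0) / t_last

    # clinical scores: baseline draw + linear change with coupled slope
    n_visits = times.shape[1]
    scores: dict[str, np.ndarray] = {}
    for m in CLINICAL_MEASURES:
        lo, hi = SCORE_BOUNDS[m]
        base = np.empty(n)
        for grp in ("case", "control"):
            mask = (participants["group"] == grp).to_numpy()
            if mask.any():
                bmu, bsd = config.clinical_baseline_distributions[m][grp]
                base[mask] = rng.normal(bmu, bsd, size=int(mask.sum()))
        base = np.clip(base, lo, hi)
        c = config.clinical_couplings[m]
        slope = (
            c.intercept
            + c.on_baseline_suvr * a0
            + c.on_dsuvr_per_year * latent_dsuvr
            + (rng.normal(0.0, c.residual_sd, size=n) if c.residual_sd > 0 else 0.0)
        )
        vals = base[:, None] + slope[:, None] * times
        if c.measurement_sd > 0:
            vals = vals + rng.normal(0.0, c.measurement_sd, size=vals.shape)
        p_miss = config.missing_rate.get(m, 0.0)
        if p_miss > 0:
            vals[rng.random(size=vals.shape) < p_miss] = np.nan
        scores[m] = vals

    visits = pd.DataFrame(
        {
            "participant_id": np.repeat(participants["id"].to_numpy(), n_visits),
            "group": np.repeat(participants["group"].to_numpy(), n_visits),
            "age": np.repeat(participants["age"].to_numpy(), n_visits),
            "sex": np.repeat(participants["sex"].to_numpy(), n_visits),
            "apoe4": np.repeat(participants["apoe4"].to_numpy(), n_visits),
            "time_years": times.ravel(),
            "suvr": suvr_obs.ravel(),
            **{m: scores[m].ravel() for m in CLINICAL_MEASURES},
        }
    )
    return participants, visits[list(VISIT_COLUMNS)]
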