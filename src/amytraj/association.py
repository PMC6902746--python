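"""Clinical-decline associations and blocked baseline group comparisons.

Two stages of the observational analysis:

* simple (unadjusted) linear regressions of each annualized clinical change
  on baseline SUVR and on annualized SUVR change, one predictor at a time —
  the association table;
* randomized-block ANOVA of baseline characteristics between the matched
  groups, with the matching block as an added fixed effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .config import CLINICAL_MEASURES

__all__ = [
    "RegressionResult",
    "fit_association",
    "association_table",
    "compare_groups_blocked",
    "TRANSFORMS",
]

PREDICTORS = ("baseline_suvr", "dsuvr_per_year")


@dataclass
class RegressionResult:
    outcome: str
    predictor: str
    coefficient: float
    se: float
    pvalue: float
    r_squared: float
    n_used: int


def fit_association(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: list[str] | None = None,
) -> RegressionResult:
    """OLS of an annualized outcome change on a single predictor.

    Complete-case, with intercept, unadjusted unless ``covariates`` are
    passed explicitly.  ``outcome`` may be a measure name (mapped to its
    d<measure>_per_year column) or a column name.
    """
    ycol = f"d{outcome}_per_year" if f"d{outcome}_per_year" in data.columns else outcome
    if ycol not in data.columns:
        raise KeyError(f"outcome column {ycol!r} not found")
    if predictor not in data.columns:
        raise KeyError(f"predictor column {predictor!r} not found")
    cols = [ycol, predictor] + list(covariates or [])
    sub = data[cols].dropna()
    if len(sub) < 3:
        raise ValueError(
            f"fewer than 3 complete cases for {outcome} ~ {predictor} ({len(sub)})"
        )
    xmat = sub[[predictor] + list(covariates or [])]
    if np.ptp(sub[predictor].to_numpy()) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    res = sm.OLS(sub[ycol], sm.add_constant(xmat)).fit()
    r2 = float(res.rsquared)
    return RegressionResult(
        outcome=outcome,
        predictor=predictor,
        coefficient=float(res.params[predictor]),
        se=float(res.bse[predictor]),
        pvalue=float(res.pvalues[predictor]),
        r_squared=r2 if np.isfinite(r2) else 0.0,  # constant outcome
        n_used=int(res.nobs),
    )


def association_table(
    data: pd.DataFrame, group: str | None = "case", group_col: str = "group"
) -> pd.DataFrame:
    """The full association table: 8 outcomes x 2 predictors, 16 rows.

    Restricted to the case group by default (the published associations are
    within the patient group); pass ``group=None`` to pool.
    """
    if group is not None:
        data = data[data[group_col] == group]
    rows = []
    for predictor in PREDICTORS:
        for m in CLINICAL_MEASURES:
            r = fit_association(data, m, predictor)
            rows.append(vars(r))
    return pd.DataFrame(
        rows,
        columns=["predictor", "outcome", "coefficient", "se", "pvalue",
                 "r_squared", "n_used"],
    )


#: named normalizing transforms for skewed baseline variables
TRANSFORMS = {
    None: lambda v: v,
    "log": np.log,
    "sqrt": np.sqrt,
    "sqrt_reflect30": lambda v: np.sqrt(30.0 - v),  # for MMSE (ceiling at 30)
}


def compare_groups_blocked(
    data: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
    block_col: str = "match_block",
    transform: str | None = None,
) -> tuple[float, float]:
    """Randomized-block ANOVA group comparison; returns (F, p) for group.

    Fits value ~ group + block with both as fixed effects and reads the
    group effect off the analysis-of-variance table.  Every block must
    contain the case and at least one control.  ``transform`` optionally
    normalizes a skewed variable first ('log', 'sqrt', 'sqrt_reflect30').
    """
    sub = data[[value_col, group_col, block_col]].dropna().copy()
    if sub.empty:
        raise ValueError("no complete observations")
    counts = sub.groupby(block_col)[group_col].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"block(s) {bad} missing the case or all controls")
    fn = TRANSFORMS[transform] if not callable(transform) else transform
    sub["_value"] = fn(sub[value_col].to_numpy(dtype=float))
    if not np.all(np.isfinite(sub["_value"])):
        raise ValueError(f"transform {transform!r} produced non-finite values")

    if np.ptp(sub["_value"].to_numpy()) == 0:
        return 0.0, 1.0
    if sub[block_col].nunique() == 1:
        model = smf.ols(f"_value ~ C({group_col})", data=sub).fit()
    else:
        model = smf.ols(f"_value ~ C({group_col}) + C({block_col})", data=sub).fit()
    table = anova_lm(model, typ=2)
    row = table.loc[f"C({group_col})"]
    f, p = float(row["F"]), float(row["PR(>F)"])
    if np.isnan(f):  # zero residual variance with zero group effect
        return 0.0, 1.0
    return f, p
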