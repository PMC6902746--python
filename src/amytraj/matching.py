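"""Greedy 4:1 nearest-age matching, exact on sex and APOE e4 carriership.

Cases are processed in ascending id order; for each, the ``ratio``
nearest-age controls in the same sex x APOE stratum and within the age
caliper are taken without replacement, ties in |age difference| broken by
ascending control id.  The procedure is deterministic and seed-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["MatchResult", "match_controls", "assign_blocks", "matches_to_frame"]


@dataclass
class MatchResult:
    case_id: str
    control_ids: list[str]
    age_differences: list[float]


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 4,
    caliper: float = 3.0,
    allow_partial: bool = False,
) -> list[MatchResult]:
    """Match ``ratio`` controls per case, exact on sex/apoe4, nearest age.

    ``cases`` and ``pool`` need columns id, age, sex, apoe4 and must be
    disjoint on id.  Raises (naming the case and stratum) when a case cannot
    be fully matched, unless ``allow_partial`` is set.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if caliper <= 0:
        raise ValueError("caliper must be > 0")
    cases = cases[["id", "age", "sex", "apoe4"]].reset_index(drop=True)
    case_ids = set(cases["id"])
    if case_ids & set(pool["id"]):
        raise ValueError("case and pool id sets overlap")

    available = pool[["id", "age", "sex", "apoe4"]].reset_index(drop=True)
    used: set[str] = set()

    results: list[MatchResult] = []
    for _, case in cases.sort_values("id").iterrows():
        stratum = available[
            (available["sex"] == case["sex"])
            & (available["apoe4"] == case["apoe4"])
            & (~available["id"].isin(used))
        ].copy()
        stratum["age_diff"] = (stratum["age"] - case["age"]).abs()
        eligible = stratum[stratum["age_diff"] <= caliper].sort_values(
            ["age_diff", "id"]
        )
        take = eligible.head(ratio)
        if len(take) < ratio and not allow_partial:
            raise ValueError(
                f"case {case['id']!r} (sex={case['sex']}, apoe4={case['apoe4']}): "
                f"only {len(take)} eligible controls within caliper "
                f"{caliper} y, {ratio} required"
            )
        used.update(take["id"])
        results.append(
            MatchResult(
                case_id=case["id"],
                control_ids=list(take["id"]),
                age_differences=list(take["age_diff"]),
            )
        )
    return results


def matches_to_frame(results: list[MatchResult]) -> pd.DataFrame:
    """Long-format table: one row per (case, control) pair."""
    rows = [
        {
            "case_id": r.case_id,
            "control_id": cid,
            "age_difference": diff,
            "match_block": r.case_id,
        }
        for r in results
        for cid, diff in zip(r.control_ids, r.age_differences)
    ]
    return pd.DataFrame(rows, columns=["case_id", "control_id", "age_difference", "match_block"])


def assign_blocks(
    participants: pd.DataFrame, results: list[MatchResult]
) -> pd.DataFrame:
    """Return the matched subset of ``participants`` with match_block filled.

    Each block is labelled by its case id and contains the case plus its
    matched controls; unmatched pool members are dropped.
    """
    block_of: dict[str, str] = {}
    for r in results:
        block_of[r.case_id] = r.case_id
        for cid in r.control_ids:
            block_of[cid] = r.case_id
    out = participants[participants["id"].isin(block_of)].copy()
    out["match_block"] = out["id"].map(block_of)
    return out.reset_index(drop=True)
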