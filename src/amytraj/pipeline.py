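"""One-command replication of the full synthetic study.

Stage order mirrors the published analysis: simulate the cohort, build the
4:1 matched control set, annualize changes, fit the rate-vs-level curves and
group tests, integrate the cumulative trajectory, run the association table
and blocked baseline comparisons, and compute the trial sample-size grid.

Every stage draws from its own deterministic substream of the single config
seed (stage-name hashed), so stages can be rerun in isolation and a repeated
run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .annualize import annualize
from .association import association_table, compare_groups_blocked
from .config import PipelineConfig
from .matching import assign_blocks, match_controls, matches_to_frame
from .power import sample_size_table
from .rates import (
    RateCurveModel,
    linearity_test,
    shape_difference_test,
    vertical_shift_test,
)
from .simulate import generate_cohort

__all__ = ["run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (stage-name hashed)."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
        .generate_state(1)[0] % (2**31)
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Execute every stage, write all artifacts, return the run manifest.

    Any stage error aborts with the stage name; artifacts of completed
    stages are left in place.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict = {"seed": config.seed, "stages": []}

    def record(name: str, *paths: Path):
        manifest["stages"].append(name)
        for p in paths:
            artifacts[p.name] = _sha256(p)

    stage = "simulate"
    try:
        gen_cfg = dataclasses.replace(
            config.generator, seed=stage_seed(config.seed, stage)
        )
        participants, visits = generate_cohort(gen_cfg)
        p_path, v_path = out / "participants.csv", out / "visits.csv"
        participants.to_csv(p_path, index=False)
        vio.write_visits(visits, v_path)
        record(stage, p_path, v_path)

        stage = "match"
        cases = participants[participants["group"] == "case"]
        pool = participants[participants["group"] == "control"]
        results = match_controls(
            cases, pool,
            ratio=config.matching.ratio,
            caliper=config.matching.caliper,
            allow_partial=config.matching.allow_partial,
        )
        matched = assign_blocks(participants, results)
        m_path = out / "matched.csv"
        matches_to_frame(results).to_csv(m_path, index=False)
        mp_path = out / "participants_matched.csv"
        matched.to_csv(mp_path, index=False)
        visits_matched = visits[visits["participant_id"].isin(matched["id"])]
        vm_path = out / "visits_matched.csv"
        vio.write_visits(visits_matched, vm_path)
        record(stage, m_path, mp_path, vm_path)
        manifest["n_participants"] = int(matched["id"].nunique())

        stage = "annualize"
        annual = annualize(visits_matched)
        a_path = out / "annualized.csv"
        annual.to_csv(a_path, index=False)
        record(stage, a_path)
        manifest["n_annualized"] = int(len(annual))

        stage = "rates"
        fits = {}
        rate_paths = []
        for label in (None, "case", "control"):
            fit = RateCurveModel(
                annual, group=label,
                n_interior_knots=config.spline.n_interior_knots,
                degree=config.spline.degree,
            ).fit(target_edf=config.spline.target_edf)
            fits[label or "pooled"] = fit
            rp = out / f"ratecurve_{label or 'pooled'}.json"
            fit.to_json(rp)
            rate_paths.append(rp)
        shape = shape_difference_test(annual)
        shift = vertical_shift_test(
            annual, target_edf=config.spline.target_edf,
            n_interior_knots=config.spline.n_interior_knots,
            degree=config.spline.degree,
        )
        lin = linearity_test(annual)
        tests = {
            "shape_difference": {"F": shape.statistic, "p": shape.pvalue},
            "vertical_shift": {
                "coefficient": shift.coefficient, "se": shift.se, "p": shift.pvalue,
            },
            "linearity": {"F": lin.statistic, "p": lin.pvalue},
        }
        t_path = out / "group_tests.json"
        t_path.write_text(json.dumps(tests, indent=1, sort_keys=True))
        record(stage, *rate_paths, t_path)

        stage = "integrate"
        pooled = fits["pooled"]
        start = config.integration.start_level
        traj = pooled.integrate(
            start_level=None if start == "auto" else float(start),
            t_max=config.integration.t_max,
            step=config.integration.step,
            epsilon=config.integration.epsilon,
        )
        tr_path = out / "trajectory.csv"
        traj.to_frame().to_csv(tr_path, index=False)
        record(stage, tr_path)
        manifest["trajectory_stop_reason"] = traj.stop_reason

        stage = "associate"
        assoc = association_table(annual)
        as_path = out / "associations.csv"
        assoc.to_csv(as_path, index=False)
        # blocked baseline comparison of (log) baseline SUVR between groups
        baseline = annual.merge(
            matched[["id", "match_block"]],
            left_on="participant_id", right_on="id",
        )
        f_stat, p_val = compare_groups_blocked(
            baseline, "baseline_suvr", transform="log"
        )
        b_path = out / "baseline_comparison.json"
        b_path.write_text(json.dumps(
            {"variable": "baseline_suvr", "transform": "log",
             "F": f_stat, "p": p_val}, indent=1, sort_keys=True))
        record(stage, as_path, b_path)

        stage = "samplesize"
        table = sample_size_table(
            config.generator,
            outcomes=list(config.power.outcomes),
            follow_ups_months=list(config.power.follow_ups_months),
            reductions=list(config.power.reductions),
            n_subjects=config.power.n_subjects,
            alpha=config.power.alpha,
            power=config.power.power,
            schedule_months=list(config.power.schedule_months),
            seed=stage_seed(config.seed, stage),
        )
        ss_path = out / "samplesize.csv"
        table.to_csv(ss_path, index=False)
        record(stage, ss_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["artifacts"] = dict(sorted(artifacts.items()))
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
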