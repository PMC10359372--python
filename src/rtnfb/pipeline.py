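"""End-to-end pipeline: simulate a cohort, replay the online engine, run the
offline learning-curve analysis and the clinical statistics, and write a
deterministic JSON report.

With a fixed seed the report is byte-identical across invocations.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import clinical_stats, io, learning_analysis, rt_engine
from .bold_sim import simulate_clinical, simulate_course
from .config import PipelineConfig
from .paradigm import ConsortFlow, build_course

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _learning_stage(config: PipelineConfig) -> dict[str, Any]:
    course = build_course(
        n_sessions=config.paradigm.n_sessions,
        tr_s=config.paradigm.tr_s,
        n_discard=config.paradigm.n_discard_online,
        up_first=config.paradigm.up_first,
    )
    analysis = dataclasses.replace(
        config.analysis, n_discard=config.paradigm.n_discard_offline
    )
    cohort = simulate_course(config.sim, course, config.n_subjects, seed=config.seed)
    per_subject = [
        learning_analysis.scores_from_runs(runs, course, analysis)
        for runs in cohort.values()
    ]
    group_curve = learning_analysis.average_half_sessions(per_subject)
    curve = learning_analysis.learning_curve(group_curve, channel="diff")

    # online engine replay of the first subject, run-level bookkeeping
    first_runs = cohort[1]
    run_summary = []
    for sim_run in first_runs[:2]:
        samples = rt_engine.run_stream(sim_run.run_spec, sim_run.target, sim_run.control)
        run_summary.append(
            {
                "run_index": sim_run.run_spec.run_index,
                "n_volumes": sim_run.run_spec.n_volumes,
                "n_samples": len(samples),
                "n_displayed": sum(s.displayed for s in samples),
            }
        )
    transfer_points = [
        {"half_session": s.half_session, "mean_diff": s.mean_diff}
        for s in group_curve
        if s.is_transfer and np.isfinite(s.mean_diff)
    ]
    return {
        "course": {
            "n_sessions": course.n_sessions,
            "n_feedback_half_sessions": course.n_feedback_runs,
            "n_transfer_half_sessions": course.n_transfer_runs,
        },
        "runs": run_summary,
        "learning_curve": {
            "r_diff": curve.r_diff,
            "p_diff": curve.p_diff,
            "slope": curve.slope,
            "r_target": curve.r_target,
            "r_control": curve.r_control,
            "r_between_curves": curve.r_between_curves,
            "n_points": curve.n_points,
        },
        "transfer_points": transfer_points,
        "group_curve": group_curve,
    }


def _clinical_stage(config: PipelineConfig) -> dict[str, Any]:
    table = simulate_clinical(config.clinical_sim)
    out: dict[str, Any] = {"anova": {}, "effect_sizes": {}, "_table": table}
    for scale in ("madrs", "bdi", "zsrds"):
        time_res, inter_res = clinical_stats.mixed_anova(table, scale)
        out["anova"][scale] = {
            r.effect: {
                "F": r.F,
                "df": [r.df_num, r.df_den],
                "p": r.p,
                "p_gg": r.p_gg,
                "gg_epsilon": r.gg_epsilon,
                "partial_eta2": r.partial_eta2,
                "eta2_ci95": list(r.eta2_ci),
            }
            for r in (time_res, inter_res)
        }
    for group in ("NFB", "CBT"):
        sub = table[table["group"] == group]
        wide = sub.pivot_table(
            index="subject_id", columns="time", values="madrs", aggfunc="first"
        ).dropna()
        g_post = clinical_stats.hedges_g(wide["post"], wide["pre"])
        g_mid = clinical_stats.hedges_g(wide["mid"], wide["pre"])
        out["effect_sizes"][group] = {
            "madrs_pre_to_post_g": g_post.g,
            "madrs_pre_to_mid_g": g_mid.g,
        }
    out["baseline_equivalence"] = {
        scale: {"p": rep["p"], "test": rep["test"]}
        for scale, rep in clinical_stats.baseline_equivalence(table).items()
    }
    out["response_remission"] = clinical_stats.response_remission(
        table,
        response_frac=config.stats.response_frac,
        remission_cutoff=config.stats.remission_cutoff,
    )
    tukey = clinical_stats.tukey_posthoc(table, "madrs")
    out["tukey_madrs"] = [
        {
            "pair": [c.level_a, c.level_b],
            "mean_diff": c.mean_diff,
            "p_adjusted": c.p_adjusted,
        }
        for c in tukey
    ]
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run all stages on simulated data and write the report to ``out_dir``.

    Writes: report.json, half_sessions.tsv, learning_curve.json, anova.json,
    effects.json, baseline.json, clinical.csv.  Returns the report dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"seed": config.seed, "config_hash": config.config_hash()}

    logger.info("pipeline stage: simulate + learn")
    learn = _learning_stage(config)
    group_curve = learn.pop("group_curve")
    with io.atomic_write(out_dir / "half_sessions.tsv") as fh:
        fh.write("half_session\tis_transfer\tmean_target\tmean_control\tmean_diff\tn_blocks\n")
        for s in group_curve:
            fh.write(
                f"{s.half_session}\t{str(s.is_transfer).lower()}\t"
                f"{io.FLOAT_FMT % s.mean_target}\t{io.FLOAT_FMT % s.mean_control}\t"
                f"{io.FLOAT_FMT % s.mean_diff}\t{s.n_blocks}\n"
            )
    io.write_json(out_dir / "learning_curve.json",
                  {**provenance, **learn["learning_curve"]})

    logger.info("pipeline stage: clinic")
    clinic = _clinical_stage(config)
    table = clinic.pop("_table")
    io.write_clinical(out_dir / "clinical.csv", table)
    io.write_json(out_dir / "anova.json", {**provenance, **clinic["anova"]})
    io.write_json(out_dir / "effects.json", {**provenance, **clinic["effect_sizes"]})
    io.write_json(out_dir / "baseline.json",
                  {**provenance, **clinic["baseline_equivalence"]})

    consort = ConsortFlow()
    consort.validate()
    report = {
        **provenance,
        "n_subjects": config.n_subjects,
        "consort": {
            "screened": consort.screened,
            "declined": consort.declined,
            "failed_screening": consort.failed_screening,
            "allocated": consort.allocated,
        },
        **{k: v for k, v in learn.items()},
        "clinical": {k: v for k, v in clinic.items()},
    }
    io.write_json(out_dir / "report.json", report)
    return report
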