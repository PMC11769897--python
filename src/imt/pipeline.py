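"""End-to-end orchestration: generate -> fit -> compare -> infer -> report.

Every output file is regenerated from the configuration and seed alone;
identical config + seed reproduces bitwise-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bms import attribute_models, protected_ep, rfx_bms
from .fit import FitSettings, estimates_to_frame, fit_hierarchical
from .io import RunConfig
from .simulate import default_cohort_spec, generate_cohort
from .stats import (
    correlation_battery,
    cronbach_alpha,
    format_anova_report,
    parameter_long_table,
    rm_anova,
    rt_long_table,
    tukey_posthoc,
)
from .task import ScheduleConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_stage", "fit_stage", "compare_stage", "stats_stage"]

SCALES = [
    "teps_anticipatory",
    "teps_consummatory",
    "sticsa_cognitive",
    "sticsa_somatic",
    "pss",
    "qids",
]


def _schedule_config(config: RunConfig) -> ScheduleConfig:
    return ScheduleConfig(
        n_trials=config.n_trials,
        effort_cap=config.effort_cap,
        extrinsic_fraction=config.extrinsic_fraction,
        effort_execution_fraction=config.effort_execution_fraction,
        seed=config.seed,
    )


def simulate_stage(config: RunConfig, outdir: Path):
    logger.info("[simulate] generating cohort (seed=%d)", config.seed)
    groups = default_cohort_spec(config.n_hc, config.n_mdd, config.n_anx)
    cohort = generate_cohort(groups, seed=config.seed, schedule_config=_schedule_config(config))
    cohort.write(outdir)
    return cohort


def fit_stage(config: RunConfig, cohort, outdir: Path) -> pd.DataFrame:
    settings = FitSettings(
        max_rounds=config.max_rounds,
        tol=config.tol,
        n_starts=config.n_starts,
        seed=config.seed,
        effort_cap=float(config.effort_cap),
    )
    frames = []
    traces = {}
    for family in config.families:
        logger.info("[fit] family=%s", family)
        estimates, prior, trace = fit_hierarchical(cohort.trials, family, settings)
        frames.append(estimates_to_frame(estimates))
        traces[family] = {
            "group_log_evidence": trace.group_log_evidence,
            "converged": trace.converged,
            "rounds_used": trace.rounds_used,
            "monotonicity_violations": trace.monotonicity_violations,
        }
    estimates = pd.concat(frames, ignore_index=True)
    estimates.to_csv(outdir / "estimates.csv", index=False)
    with open(outdir / "trace.json", "w") as fh:
        json.dump(traces, fh, indent=1)
    return estimates


def compare_stage(config: RunConfig, estimates: pd.DataFrame, outdir: Path):
    logger.info("[compare] random-effects BMS over %s", config.families)
    # per-subject evidence summed over the four conditions, per family
    ev = (
        estimates.groupby(["subject_id", "family"])["log_evidence"]
        .sum()
        .unstack("family")
        .loc[:, config.families]
    )
    bms = rfx_bms(
        ev.to_numpy(),
        families=config.families,
        n_samples=config.bms_samples,
        seed=config.seed,
    )
    bms = protected_ep(bms, ev.to_numpy())
    attributions = attribute_models(bms, subject_ids=list(ev.index))
    attributions.to_csv(outdir / "bms_summary.csv", index=False)
    payload = {
        "families": bms.families,
        "alpha": bms.alpha.tolist(),
        "expected_frequencies": bms.expected_frequencies.tolist(),
        "exceedance_probability": bms.exceedance_probability.tolist(),
        "bor": bms.bor,
        "protected_exceedance_probability": bms.protected_exceedance_probability.tolist(),
        "metadata": {"alpha0": bms.alpha0, **bms.metadata},
    }
    with open(outdir / "bms.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    return bms


def stats_stage(config: RunConfig, estimates: pd.DataFrame, cohort, outdir: Path):
    logger.info("[stats] winning-family parameter statistics")
    sig = estimates[estimates["family"] == "sigmoid"]
    subjects = cohort.subjects
    has_group = subjects["group"].nunique() > 1

    anova_frames = []
    posthoc_frames = []
    report_lines = []
    for measure in ("bias", "sigma"):
        table = parameter_long_table(sig, subjects, measure)
        anova = rm_anova(
            table,
            dv=measure,
            within=["control", "valence"],
            between="group" if has_group else None,
        )
        anova.insert(0, "dv", measure)
        anova_frames.append(anova)
        report_lines.append(format_anova_report(anova, measure))
        if has_group:
            ph = tukey_posthoc(table, dv=measure, factor="group")
            ph.insert(0, "dv", measure)
            posthoc_frames.append(ph)

    rt = rt_long_table(cohort.trials, subjects)
    anova_rt = rm_anova(
        rt,
        dv="reaction_time",
        within=["control", "valence"],
        between="group" if has_group else None,
    )
    anova_rt.insert(0, "dv", "reaction_time")
    anova_frames.append(anova_rt)
    report_lines.append(format_anova_report(anova_rt, "reaction_time"))

    pd.concat(anova_frames, ignore_index=True).to_csv(outdir / "anova.csv", index=False)
    if posthoc_frames:
        pd.concat(posthoc_frames, ignore_index=True).to_csv(
            outdir / "posthoc.csv", index=False
        )

    corr_frames = []
    for measure in ("bias", "sigma"):
        corr_frames.append(
            correlation_battery(sig, subjects, measure, SCALES, alpha=config.alpha)
        )
    correlations = pd.concat(corr_frames, ignore_index=True)
    correlations.to_csv(outdir / "correlations.csv", index=False)

    # internal consistency across the four condition "items"
    reliability = {}
    for measure in ("bias", "sigma"):
        wide = sig.pivot(index="subject_id", columns="condition", values=measure)
        reliability[f"cronbach_alpha_{measure}"] = cronbach_alpha(wide.to_numpy())
    with open(outdir / "reliability.json", "w") as fh:
        json.dump(reliability, fh, indent=1)

    (outdir / "report.txt").write_text("\n\n".join(report_lines) + "\n")
    return {
        "anova": pd.concat(anova_frames, ignore_index=True),
        "correlations": correlations,
        "reliability": reliability,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages in order; returns the artifact directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = simulate_stage(config, outdir)
    estimates = fit_stage(config, cohort, outdir)
    compare_stage(config, estimates, outdir)
    stats_stage(config, estimates, cohort, outdir)

    cfg_hash = hashlib.sha256(
        json.dumps(config.__dict__, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "config": config.__dict__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "versions": {
            "imt": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return outdir
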