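"""Synthetic IMT cohorts with group structure and symptom couplings.

No trial-level data are distributed with the study this pipeline models, so
every downstream stage (hierarchical fitting, model selection, group
statistics) is exercised on synthetic cohorts whose *structure* matches the
study design: three groups (healthy controls HC, major depressive disorder
MDD, anxiety/stress disorders ANX), a 2x2 within-subject design (control
condition x valence), six self-report symptom scales, and covariates (age,
sex, psychoactive medication).

Subject-level discount curves are sigmoid; group means encode the reported
effect directions -- MDD: higher extrinsic bias (lower extrinsic motivation)
and higher loss bias (lower motivation to avoid losses); ANX: the opposite
on both, plus higher intrinsic sigma (outcome insensitivity under intrinsic
control).  Default separations are ~0.4 between-subject SDs; the magnitudes
are free design knobs, documented in docs/methods.md, chosen only to make
the effect structure detectable and testable.

Symptom scores are truncated normal within each instrument's range with
linear Gaussian couplings to curve parameters expressed as target
correlations (e.g. anticipatory-pleasure scores correlate negatively with
extrinsic bias: less anticipatory pleasure, less extrinsic motivation).
Reaction times are lognormal with additive log-scale offsets: intrinsic
choices slower than extrinsic, losses slower than wins, MDD slowest and ANX
fastest overall.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit

from .curves import CurveParams, Family, ObservationParams, eval_curve
from .task import Control, ScheduleConfig, TaskSchedule, build_schedule

__all__ = [
    "CONDITIONS",
    "GroupSpec",
    "CohortData",
    "default_cohort_spec",
    "draw_subject",
    "simulate_responses",
    "generate_cohort",
    "find_deterministic_responders",
]

#: the four subject-level fitting conditions (control x valence)
CONDITIONS: tuple[str, ...] = (
    "extrinsic-win",
    "extrinsic-loss",
    "intrinsic-win",
    "intrinsic-loss",
)

#: instrument score ranges (min, max) on their native scales
SCALE_RANGES: dict[str, tuple[float, float]] = {
    "teps_anticipatory": (10, 60),
    "teps_consummatory": (8, 48),
    "sticsa_cognitive": (10, 40),
    "sticsa_somatic": (11, 44),
    "pss": (0, 40),
    "qids": (0, 27),
}

# between-subject SD of the bias parameter; group offsets below are ~0.4 SD
_BIAS_SD = 0.15
_EFFECT = 0.06


def _bias_means(ext_shift: float, loss_shift: float) -> dict[str, float]:
    base = {
        "extrinsic-win": 0.45,
        "extrinsic-loss": 0.50,
        "intrinsic-win": 0.55,
        "intrinsic-loss": 0.60,
    }
    out = {}
    for cond, mu in base.items():
        mu += ext_shift if cond.startswith("extrinsic") else 0.0
        mu += loss_shift if cond.endswith("loss") else 0.0
        out[cond] = mu
    return out


def _sigma_means(intrinsic_shift: float = 0.0) -> dict[str, float]:
    base = {
        "extrinsic-win": 0.10,
        "extrinsic-loss": 0.12,
        "intrinsic-win": 0.14,
        "intrinsic-loss": 0.16,
    }
    return {
        c: mu + (intrinsic_shift if c.startswith("intrinsic") else 0.0)
        for c, mu in base.items()
    }


@dataclass
class GroupSpec:
    """Generative description of one diagnostic group."""

    label: str
    n_subjects: int
    bias_mean: dict[str, float]
    sigma_mean: dict[str, float]
    bias_sd: float = _BIAS_SD
    sigma_sd: float = 0.04
    #: fraction of between-subject parameter variance shared across the four
    #: conditions (a stable subject-level trait); bias behaves as a more
    #: trait-like measure than sigma, mirroring its higher internal consistency
    bias_trait_frac: float = 0.59
    sigma_trait_frac: float = 0.35
    asymptote_mean: float = 52.5
    asymptote_sd: float = 8.0
    tau_mean: float = 4.0
    tau_sd: float = 1.0
    sigma_obs_mean: float = 5.0
    sigma_obs_sd: float = 1.5
    age_mean: float = 32.0
    age_sd: float = 10.0
    female_prob: float = 0.6
    medication_prob: float = 0.0
    symptom_means: dict[str, float] = field(default_factory=dict)
    symptom_sds: dict[str, float] = field(default_factory=dict)
    #: list of (scale, condition, parameter, target correlation)
    couplings: list[tuple[str, str, str, float]] = field(default_factory=list)
    rt_log_offset: float = 0.0
    effort_cap: float = 70.0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("bias_sd", "sigma_sd", "asymptote_sd", "tau_sd", "sigma_obs_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("bias_trait_frac", "sigma_trait_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for cond in CONDITIONS:
            if cond not in self.bias_mean or cond not in self.sigma_mean:
                raise ValueError(f"missing parameter means for condition {cond}")
        per_scale: dict[str, float] = {}
        for scale, cond, par, rho in self.couplings:
            if scale not in SCALE_RANGES:
                raise ValueError(f"unknown scale {scale}")
            if cond not in CONDITIONS or par not in ("bias", "sigma"):
                raise ValueError(f"bad coupling target {cond}/{par}")
            per_scale[scale] = per_scale.get(scale, 0.0) + rho * rho
        for scale, ss in per_scale.items():
            if ss > 1.0:
                raise ValueError(f"couplings for {scale} imply correlation > 1")


_BASE_SYMPTOMS = {
    "teps_anticipatory": (45.0, 7.0),
    "teps_consummatory": (36.0, 6.0),
    "sticsa_cognitive": (18.0, 5.0),
    "sticsa_somatic": (19.0, 5.0),
    "pss": (16.0, 6.0),
    "qids": (5.0, 3.0),
}

_GROUP_SYMPTOM_SHIFTS = {
    "HC": {},
    "MDD": {
        "teps_anticipatory": -6.0,
        "teps_consummatory": -5.0,
        "sticsa_cognitive": 6.0,
        "sticsa_somatic": 4.0,
        "pss": 6.0,
        "qids": 8.0,
    },
    "ANX": {
        "teps_anticipatory": -2.0,
        "sticsa_cognitive": 8.0,
        "sticsa_somatic": 7.0,
        "pss": 4.0,
        "qids": 4.0,
    },
}

_DEFAULT_COUPLINGS = [
    ("teps_anticipatory", "extrinsic-win", "bias", -0.2),
    ("teps_anticipatory", "extrinsic-loss", "bias", -0.2),
    ("teps_consummatory", "intrinsic-win", "sigma", -0.3),
    ("teps_consummatory", "intrinsic-loss", "sigma", -0.25),
]


def default_cohort_spec(
    n_hc: int = 74, n_mdd: int = 63, n_anx: int = 44
) -> list[GroupSpec]:
    """Three-group cohort with the study's effect directions.

    Group sizes default to the analysed in-person cohort (74/63/44).
    """

    def symptoms(label):
        means = {
            k: v[0] + _GROUP_SYMPTOM_SHIFTS[label].get(k, 0.0)
            for k, v in _BASE_SYMPTOMS.items()
        }
        sds = {k: v[1] for k, v in _BASE_SYMPTOMS.items()}
        return means, sds

    groups = []
    for label, n, ext, loss, sig_int, med_p, rt_off in [
        ("HC", n_hc, 0.0, 0.0, 0.0, 0.0, 0.0),
        ("MDD", n_mdd, +_EFFECT, +_EFFECT, 0.0, 0.6, +0.08),
        ("ANX", n_anx, -_EFFECT, -_EFFECT, +0.016, 0.5, -0.08),
    ]:
        means, sds = symptoms(label)
        groups.append(
            GroupSpec(
                label=label,
                n_subjects=n,
                bias_mean=_bias_means(ext, loss),
                sigma_mean=_sigma_means(sig_int),
                medication_prob=med_p,
                symptom_means=means,
                symptom_sds=sds,
                couplings=copy.deepcopy(_DEFAULT_COUPLINGS),
                rt_log_offset=rt_off,
            )
        )
    return groups


def _truncated_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(64):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(v, lo, hi))


def draw_subject(group: GroupSpec, rng: np.random.Generator) -> dict[str, Any]:
    """Draw one subject's true curve parameters, covariates and symptoms.

    Curve parameters are sigmoid per condition.  Symptom scores are built
    from the standardized deviations of the coupled parameters so that the
    configured target correlations hold in expectation, then truncated to
    each instrument's valid range.
    """
    group.validate()
    params: dict[str, CurveParams] = {}
    z: dict[tuple[str, str], float] = {}  # (condition, par) -> z-score of draw
    # subject-level trait components shared across conditions
    trait_bias = rng.standard_normal()
    trait_sigma = rng.standard_normal()
    wb, ws = math.sqrt(group.bias_trait_frac), math.sqrt(group.sigma_trait_frac)
    for cond in CONDITIONS:
        zb = wb * trait_bias + math.sqrt(1.0 - group.bias_trait_frac) * rng.standard_normal()
        bias = group.bias_mean[cond] + group.bias_sd * zb
        zs = ws * trait_sigma + math.sqrt(1.0 - group.sigma_trait_frac) * rng.standard_normal()
        sigma = group.sigma_mean[cond] + group.sigma_sd * zs
        sigma = max(sigma, 0.02)
        c = _truncated_normal(
            rng, group.asymptote_mean, group.asymptote_sd, 5.0, group.effort_cap
        )
        z[(cond, "bias")] = zb
        z[(cond, "sigma")] = zs
        params[cond] = CurveParams(
            family=Family.SIGMOID,
            c=c,
            bias=bias,
            sigma=sigma,
            effort_cap=group.effort_cap,
        )

    obs = ObservationParams(
        choice_temperature=_truncated_normal(
            rng, group.tau_mean, group.tau_sd, 0.5, 20.0
        ),
        intrinsic_sd=_truncated_normal(
            rng, group.sigma_obs_mean, group.sigma_obs_sd, 0.5, 20.0
        ),
    )

    symptoms: dict[str, float] = {}
    by_scale: dict[str, list[tuple[str, str, float]]] = {}
    for scale, cond, par, rho in group.couplings:
        by_scale.setdefault(scale, []).append((cond, par, rho))
    for scale, (lo, hi) in SCALE_RANGES.items():
        mu = group.symptom_means.get(scale, (lo + hi) / 2)
        sd = group.symptom_sds.get(scale, (hi - lo) / 8)
        links = by_scale.get(scale, [])
        signal = sum(rho * z[(cond, par)] for cond, par, rho in links)
        resid_var = 1.0 - sum(rho * rho for _, _, rho in links)
        zz = signal + math.sqrt(max(resid_var, 0.0)) * rng.standard_normal()
        symptoms[scale] = float(np.clip(mu + sd * zz, lo, hi))

    return {
        "group": group.label,
        "params": params,
        "obs": obs,
        "age": _truncated_normal(rng, group.age_mean, group.age_sd, 18, 65),
        "sex": "F" if rng.random() < group.female_prob else "M",
        "medication": bool(rng.random() < group.medication_prob),
        "symptoms": symptoms,
        "rt_log_offset": group.rt_log_offset,
    }


# log-scale reaction-time offsets: intrinsic choices are slower, losses
# slightly slower; base is the extrinsic-win geometric mean in seconds
_RT_LOG_BASE = math.log(1.2)
_RT_LOG_INTRINSIC = 0.5
_RT_LOG_LOSS = 0.05
_RT_LOG_SD = 0.30


def simulate_responses(
    true_params: dict[str, CurveParams],
    obs: ObservationParams,
    schedule: TaskSchedule,
    rng: np.random.Generator,
    rt_log_offset: float = 0.0,
) -> pd.DataFrame:
    """Simulate one subject's trial-level responses on a schedule.

    Extrinsic trials: accept with the logistic choice probability implied by
    the curve and temperature tau.  Intrinsic trials: the curve value plus
    Gaussian report noise, clamped to [0, effort_cap] and rounded to integer
    presses.  Reaction times are lognormal with condition offsets.
    """
    obs.validate()
    cap = schedule.effort_cap
    rows = []
    for i, t in enumerate(schedule.trials):
        cond = f"{t.control.value}-{t.valence.value}"
        y = float(eval_curve(true_params[cond], t.outcome_norm))
        accepted: bool | None = None
        reported: float | None = None
        if t.control == Control.EXTRINSIC:
            p = float(expit((y - t.offered_effort) / obs.choice_temperature))
            accepted = bool(rng.random() < p)
        else:
            raw = y + obs.intrinsic_sd * rng.standard_normal()
            reported = float(np.clip(round(raw), 0, cap))
        log_rt = (
            _RT_LOG_BASE
            + (_RT_LOG_INTRINSIC if t.control == Control.INTRINSIC else 0.0)
            + (_RT_LOG_LOSS if t.valence.value == "loss" else 0.0)
            + rt_log_offset
            + _RT_LOG_SD * rng.standard_normal()
        )
        rows.append(
            {
                "trial_index": i,
                "control": t.control.value,
                "valence": t.valence.value,
                "outcome_type": t.outcome_type.value,
                "outcome_magnitude": t.outcome_magnitude,
                "outcome_norm": t.outcome_norm,
                "offered_effort": t.offered_effort,
                "executes_effort": t.executes_effort,
                "accepted": accepted,
                "reported_effort": reported,
                "reaction_time": math.exp(log_rt),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CohortData:
    """A generated cohort: subject table, trial table, truth manifest."""

    subjects: pd.DataFrame
    trials: pd.DataFrame
    truth: dict[str, Any]
    schedule: TaskSchedule

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(outdir / "subjects.csv", index=False)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def generate_cohort(
    groups: list[GroupSpec],
    seed: int,
    schedule_config: ScheduleConfig | None = None,
) -> CohortData:
    """Generate a full cohort: one shared schedule, per-subject responses.

    Returns subject and trial tables plus a manifest of the true generating
    parameters (for recovery testing).  Identical seeds reproduce identical
    tables; different seeds share the design columns and differ only in the
    stochastic response columns (given the same schedule config).
    """
    for g in groups:
        g.validate()
    schedule_config = schedule_config or ScheduleConfig()
    schedule = build_schedule(schedule_config)
    rng = np.random.default_rng(seed)

    subj_rows = []
    trial_frames = []
    truth_subjects: dict[str, Any] = {}
    idx = 0
    for g in groups:
        for _ in range(g.n_subjects):
            sid = f"S{idx:04d}"
            idx += 1
            subj = draw_subject(g, rng)
            resp = simulate_responses(
                subj["params"], subj["obs"], schedule, rng, subj["rt_log_offset"]
            )
            resp.insert(0, "subject_id", sid)
            trial_frames.append(resp)
            row = {
                "subject_id": sid,
                "group": subj["group"],
                "age": subj["age"],
                "sex": subj["sex"],
                "medication": subj["medication"],
            }
            row.update(subj["symptoms"])
            subj_rows.append(row)
            truth_subjects[sid] = {
                "group": subj["group"],
                "tau": subj["obs"].choice_temperature,
                "sigma_obs": subj["obs"].intrinsic_sd,
                "params": {
                    cond: {"bias": p.bias, "sigma": p.sigma, "c": p.c}
                    for cond, p in subj["params"].items()
                },
            }

    subjects = pd.DataFrame(subj_rows)
    trials = pd.concat(trial_frames, ignore_index=True)
    deterministic = find_deterministic_responders(trials)
    truth = {
        "seed": seed,
        "effort_cap": schedule.effort_cap,
        "n_subjects": len(subjects),
        "deterministic_responders": deterministic,
        "subjects": truth_subjects,
    }
    return CohortData(subjects=subjects, trials=trials, truth=truth, schedule=schedule)


def find_deterministic_responders(trials: pd.DataFrame) -> list[str]:
    """Subjects giving the same button response on every extrinsic trial
    (all-accept or all-reject), mirroring the study's exclusion rule."""
    out = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        ext = sub[sub["control"] == "extrinsic"]["accepted"].dropna()
        if len(ext) > 0 and ext.nunique() == 1:
            out.append(str(sid))
    return out
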