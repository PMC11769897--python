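"""Dataset reading, schema validation and run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["Dataset", "RunConfig", "read_dataset", "SUBJECT_COLUMNS", "TRIAL_COLUMNS"]

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "medication",
    "teps_anticipatory",
    "teps_consummatory",
    "sticsa_cognitive",
    "sticsa_somatic",
    "pss",
    "qids",
]

TRIAL_COLUMNS = [
    "subject_id",
    "trial_index",
    "control",
    "valence",
    "outcome_type",
    "outcome_magnitude",
    "outcome_norm",
    "offered_effort",
    "executes_effort",
    "accepted",
    "reported_effort",
    "reaction_time",
]


@dataclass
class Dataset:
    subjects: pd.DataFrame
    trials: pd.DataFrame
    #: subjects giving the same button response on every extrinsic trial
    deterministic_responders: list[str] = field(default_factory=list)


def _check_schema(df: pd.DataFrame, expected: list[str], name: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise ValueError(
            f"{name} schema mismatch: missing columns {missing}, extra columns {extra}"
        )


def read_dataset(subjects_path, trials_path, effort_cap: float = 70.0) -> Dataset:
    """Read and validate a subjects/trials CSV pair.

    Deterministic responders (the study's exclusion rule) are flagged, not
    dropped; the fitting stage excludes them.
    """
    from .simulate import find_deterministic_responders

    subjects = pd.read_csv(subjects_path)
    trials = pd.read_csv(trials_path)
    _check_schema(subjects, SUBJECT_COLUMNS, "subjects")
    _check_schema(trials, TRIAL_COLUMNS, "trials")
    if len(trials) == 0:
        raise ValueError("empty trials file")

    offered = trials["offered_effort"].dropna()
    if ((offered < 1) | (offered > effort_cap)).any():
        raise ValueError(f"offered_effort outside [1, {effort_cap}]")
    reported = trials["reported_effort"].dropna()
    if ((reported < 0) | (reported > effort_cap)).any():
        raise ValueError(f"reported_effort outside [0, {effort_cap}]")

    return Dataset(
        subjects=subjects,
        trials=trials,
        deterministic_responders=find_deterministic_responders(trials),
    )


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    seed: int
    outdir: str = "results/run"
    n_hc: int = 74
    n_mdd: int = 63
    n_anx: int = 44
    n_trials: int = 228
    effort_cap: int = 70
    extrinsic_fraction: float = 0.75
    effort_execution_fraction: float = 0.30
    families: list[str] = field(default_factory=lambda: ["linear", "sigmoid", "weibull"])
    max_rounds: int = 16
    tol: float = 0.01
    n_starts: int = 4
    bms_samples: int = 1_000_000
    alpha: float = 0.05
    one_sided_corr_diff: bool = True

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        payload = {k: v for k, v in self.__dict__.items()}
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
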