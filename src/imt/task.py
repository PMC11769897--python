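"""Trial structure of the Internal-external Motivation Task (IMT).

The IMT is an effort-based decision task with two control conditions:

* **extrinsic** -- the environment offers an effort level (button presses)
  for an offered outcome and the participant accepts or rejects the offer;
* **intrinsic** -- the participant self-generates the effort level they are
  willing to exert for the offered outcome (up to an effort cap).

Outcomes are monetary ($0.25-$2.00) or social (25-200 points), each either a
win or a loss, crossed evenly over the session.  A fixed fraction of trials
is randomly designated to actually require the effort to be performed.

This module builds and validates task schedules; the simulator and the
fitting code consume :class:`TaskSchedule` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Control",
    "Valence",
    "OutcomeType",
    "TrialSpec",
    "ScheduleConfig",
    "TaskSchedule",
    "build_schedule",
    "normalize_outcome",
    "validate_schedule",
]


class Control(str, Enum):
    EXTRINSIC = "extrinsic"
    INTRINSIC = "intrinsic"


class Valence(str, Enum):
    WIN = "win"
    LOSS = "loss"


class OutcomeType(str, Enum):
    MONEY = "money"
    SOCIAL = "social"


#: native-scale outcome levels: 8 equally spaced values spanning the task ranges
DEFAULT_MONEY_LEVELS: tuple[float, ...] = tuple(np.linspace(0.25, 2.00, 8).round(2))
DEFAULT_SOCIAL_LEVELS: tuple[float, ...] = tuple(np.linspace(25, 200, 8).round(0))
#: offered effort levels (extrinsic trials): 6 equally spaced integer levels
DEFAULT_EFFORT_LEVELS: tuple[int, ...] = (10, 22, 34, 46, 58, 70)

DEFAULT_EFFORT_CAP = 70
DEFAULT_N_TRIALS = 228
DEFAULT_EXTRINSIC_FRACTION = 0.75  # 3:1 extrinsic:intrinsic
DEFAULT_EXECUTION_FRACTION = 0.30


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the IMT.

    ``offered_effort`` is present iff the trial is under extrinsic control.
    ``outcome_norm`` is the outcome magnitude rescaled so that the maximum of
    its outcome type maps to 1.0, giving money and social trials a common
    x-axis for curve fitting.
    """

    control: Control
    valence: Valence
    outcome_type: OutcomeType
    outcome_magnitude: float
    outcome_norm: float
    offered_effort: int | None = None
    executes_effort: bool = False


@dataclass
class ScheduleConfig:
    """Configuration of :func:`build_schedule`."""

    n_trials: int = DEFAULT_N_TRIALS
    effort_cap: int = DEFAULT_EFFORT_CAP
    extrinsic_fraction: float = DEFAULT_EXTRINSIC_FRACTION
    effort_execution_fraction: float = DEFAULT_EXECUTION_FRACTION
    money_levels: Sequence[float] = DEFAULT_MONEY_LEVELS
    social_levels: Sequence[float] = DEFAULT_SOCIAL_LEVELS
    effort_levels: Sequence[int] = DEFAULT_EFFORT_LEVELS
    #: if True, refuse trial totals that cannot split evenly over the four cells
    require_even_split: bool = False
    seed: int = 0


@dataclass
class TaskSchedule:
    trials: list[TrialSpec]
    effort_cap: int = DEFAULT_EFFORT_CAP
    effort_execution_fraction: float = DEFAULT_EXECUTION_FRACTION
    config_seed: int = 0

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.trials):
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
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "effort_cap": self.effort_cap,
            "effort_execution_fraction": self.effort_execution_fraction,
            "config_seed": self.config_seed,
            "trials": self.to_frame().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        effort_cap: int = DEFAULT_EFFORT_CAP,
        effort_execution_fraction: float = DEFAULT_EXECUTION_FRACTION,
        config_seed: int = 0,
    ) -> "TaskSchedule":
        trials = []
        for _, r in frame.sort_values("trial_index").iterrows():
            offered = r["offered_effort"]
            offered = None if pd.isna(offered) else int(offered)
            trials.append(
                TrialSpec(
                    control=Control(r["control"]),
                    valence=Valence(r["valence"]),
                    outcome_type=OutcomeType(r["outcome_type"]),
                    outcome_magnitude=float(r["outcome_magnitude"]),
                    outcome_norm=float(r["outcome_norm"]),
                    offered_effort=offered,
                    executes_effort=bool(r["executes_effort"]),
                )
            )
        return cls(trials, effort_cap, effort_execution_fraction, config_seed)


def normalize_outcome(
    magnitude: float,
    outcome_type: OutcomeType | str,
    config: ScheduleConfig | None = None,
) -> float:
    """Map a native-scale outcome to the common (0, 1] axis.

    The maximum configured level of each outcome type maps to 1.0 and the
    mapping is linear through zero, so $2.00 and 200 social points land on
    the same point of the fitted discount curve's x-axis.
    """
    config = config or ScheduleConfig()
    outcome_type = OutcomeType(outcome_type)
    levels = (
        config.money_levels if outcome_type == OutcomeType.MONEY else config.social_levels
    )
    lo, hi = min(levels), max(levels)
    if not (lo <= magnitude <= hi):
        raise ValueError(
            f"{outcome_type.value} magnitude {magnitude} outside configured range [{lo}, {hi}]"
        )
    return float(magnitude) / float(hi)


def build_schedule(config: ScheduleConfig | None = None) -> TaskSchedule:
    """Build a randomly ordered IMT schedule.

    Trials are split evenly over the four (valence x outcome-type) cells;
    within each cell the extrinsic:intrinsic ratio follows
    ``config.extrinsic_fraction`` (rounded to integers).  Outcome and effort
    levels cycle deterministically through the configured grids before the
    whole list is shuffled, so identical seeds yield identical orderings and
    different seeds yield permutations of the same trial multiset.
    """
    config = config or ScheduleConfig()
    if config.n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not config.money_levels or not config.social_levels or not config.effort_levels:
        raise ValueError("outcome and effort level lists must be non-empty")
    bad = [e for e in config.effort_levels if not (1 <= e <= config.effort_cap)]
    if bad:
        raise ValueError(
            f"effort levels {bad} outside [1, effort_cap={config.effort_cap}]"
        )

    cells = [(v, o) for v in Valence for o in OutcomeType]
    if config.require_even_split and config.n_trials % len(cells) != 0:
        base = config.n_trials // len(cells)
        rem = config.n_trials % len(cells)
        counts = {
            f"{v.value}-{o.value}": base + (1 if i < rem else 0)
            for i, (v, o) in enumerate(cells)
        }
        raise ValueError(
            f"{config.n_trials} trials cannot split evenly over the four "
            f"valence-by-outcome-type cells; closest split would be {counts}"
        )
    if config.n_trials % len(cells) == 0:
        per_cell = [config.n_trials // len(cells)] * len(cells)
    else:
        base = config.n_trials // len(cells)
        rem = config.n_trials % len(cells)
        if config.n_trials >= len(cells):
            per_cell = [base + (1 if i < rem else 0) for i in range(len(cells))]
        else:
            per_cell = [1 if i < config.n_trials else 0 for i in range(len(cells))]

    rng = np.random.default_rng(config.seed)
    trials: list[TrialSpec] = []
    for (valence, otype), n_cell in zip(cells, per_cell):
        if n_cell == 0:
            continue
        levels = (
            config.money_levels if otype == OutcomeType.MONEY else config.social_levels
        )
        n_ext = int(round(config.extrinsic_fraction * n_cell))
        n_int = n_cell - n_ext
        # deterministic cycling through the outcome-by-effort grid
        for i in range(n_ext):
            mag = levels[i % len(levels)]
            eff = config.effort_levels[(i // len(levels)) % len(config.effort_levels)]
            trials.append(
                TrialSpec(
                    control=Control.EXTRINSIC,
                    valence=valence,
                    outcome_type=otype,
                    outcome_magnitude=float(mag),
                    outcome_norm=normalize_outcome(mag, otype, config),
                    offered_effort=int(eff),
                )
            )
        for i in range(n_int):
            mag = levels[i % len(levels)]
            trials.append(
                TrialSpec(
                    control=Control.INTRINSIC,
                    valence=valence,
                    outcome_type=otype,
                    outcome_magnitude=float(mag),
                    outcome_norm=normalize_outcome(mag, otype, config),
                )
            )

    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]

    n_exec = int(round(config.effort_execution_fraction * len(trials)))
    exec_idx = set(rng.choice(len(trials), size=n_exec, replace=False).tolist())
    trials = [
        TrialSpec(
            control=t.control,
            valence=t.valence,
            outcome_type=t.outcome_type,
            outcome_magnitude=t.outcome_magnitude,
            outcome_norm=t.outcome_norm,
            offered_effort=t.offered_effort,
            executes_effort=(i in exec_idx),
        )
        for i, t in enumerate(trials)
    ]
    return TaskSchedule(
        trials,
        effort_cap=config.effort_cap,
        effort_execution_fraction=config.effort_execution_fraction,
        config_seed=config.seed,
    )


def validate_schedule(schedule: TaskSchedule) -> list[str]:
    """Return a list of invariant violations (empty iff the schedule is valid).

    Validation never raises; every violated invariant is reported by name.
    """
    report: list[str] = []
    n = len(schedule.trials)
    if n == 0:
        report.append("schedule has no trials")
        return report

    counts: dict[tuple[str, str], int] = {}
    for i, t in enumerate(schedule.trials):
        counts[(t.valence.value, t.outcome_type.value)] = (
            counts.get((t.valence.value, t.outcome_type.value), 0) + 1
        )
        if t.control == Control.EXTRINSIC:
            if t.offered_effort is None:
                report.append(f"trial {i}: extrinsic trial without offered_effort")
            elif t.offered_effort > schedule.effort_cap:
                report.append(
                    f"trial {i}: offered_effort {t.offered_effort} exceeds "
                    f"effort_cap {schedule.effort_cap}"
                )
        else:
            if t.offered_effort is not None:
                report.append(f"trial {i}: intrinsic trial carries offered_effort")
        if not (0.0 < t.outcome_norm <= 1.0):
            report.append(f"trial {i}: outcome_norm {t.outcome_norm} outside (0, 1]")

    if n % 4 == 0 and len(set(counts.values())) > 1:
        report.append(f"unequal valence-by-outcome-type cell counts: {counts}")

    n_exec = sum(t.executes_effort for t in schedule.trials)
    expected = int(round(schedule.effort_execution_fraction * n))
    if n_exec != expected:
        report.append(
            f"executes_effort count {n_exec} != round(fraction*total) = {expected}"
        )
    return report
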