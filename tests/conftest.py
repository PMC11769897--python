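"""Shared fixtures.

The expensive hierarchical fits are session-scoped so the recovery,
shrinkage, evidence-trace and model-selection checks all reuse one fit.
Problem sizes are scaled for a single-CPU run (documented in
docs/methods.md); the scientific claims they support are scale-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from imt.fit import FitSettings, estimates_to_frame, fit_hierarchical
from imt.simulate import default_cohort_spec, generate_cohort


def attach_truth(frame: pd.DataFrame, truth: dict) -> pd.DataFrame:
    frame = frame.copy()
    subs = truth["subjects"]
    frame["true_bias"] = [
        subs[s]["params"][c]["bias"] for s, c in zip(frame.subject_id, frame.condition)
    ]
    frame["true_sigma"] = [
        subs[s]["params"][c]["sigma"] for s, c in zip(frame.subject_id, frame.condition)
    ]
    return frame


@pytest.fixture(scope="session")
def recovery_cohort():
    """40 subjects (20/12/8 across groups), full 228-trial sessions."""
    return generate_cohort(default_cohort_spec(20, 12, 8), seed=11)


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    """Hierarchical sigmoid fit of the recovery cohort."""
    settings = FitSettings(max_rounds=6, seed=11)
    estimates, prior, trace = fit_hierarchical(
        recovery_cohort.trials, "sigmoid", settings
    )
    return estimates, prior, trace


@pytest.fixture(scope="session")
def no_pooling_fit(recovery_cohort):
    """Round-1 (broad initial prior) sigmoid fit for shrinkage comparison."""
    settings = FitSettings(max_rounds=1, seed=11)
    estimates, _, _ = fit_hierarchical(recovery_cohort.trials, "sigmoid", settings)
    return estimates


@pytest.fixture(scope="session")
def recovery_frame(recovery_cohort, recovery_fit):
    estimates, _, _ = recovery_fit
    return attach_truth(estimates_to_frame(estimates), recovery_cohort.truth)


@pytest.fixture(scope="session")
def family_comparison():
    """30-subject sigmoid-generated cohort fit with all three families.

    Returns (families, subject-by-family log-evidence matrix).
    """
    cohort = generate_cohort(default_cohort_spec(15, 9, 6), seed=7)
    settings = FitSettings(max_rounds=3, seed=7)
    families = ["linear", "sigmoid", "weibull"]
    frames = []
    for fam in families:
        estimates, _, _ = fit_hierarchical(cohort.trials, fam, settings)
        frames.append(estimates_to_frame(estimates))
    df = pd.concat(frames, ignore_index=True)
    ev = (
        df.groupby(["subject_id", "family"])["log_evidence"]
        .sum()
        .unstack("family")
        .loc[:, families]
    )
    return families, ev.to_numpy()
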