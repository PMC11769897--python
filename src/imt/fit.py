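"""Hierarchical (empirical-Bayes) curve fitting with Laplace evidence.

Each subject x condition is fit by MAP estimation in a transformed
parameter space (positivity-constrained parameters on the log scale, the
sigmoid bias untransformed so it can sit outside (0, 1) for never/always
motivated subjects), with the posterior covariance taken from the Hessian
at the optimum and the log model evidence from the Laplace approximation

    log p(data) ~= log p(data | th) + log p(th) + (d/2) log 2pi - 1/2 log|H|

where ``H`` is the Hessian of the negative log joint at the MAP ``th``.

Fitting is mixed-effects: after one round of subject-level fits, the
population distribution (mean of posterior means; between-subject
covariance of the means plus the average within-subject covariance) becomes
the prior for the next round, iterated until the summed log evidence stops
improving.  This parametric empirical-Bayes loop shrinks individual
estimates toward the group mean, which damps outlier parameter estimates.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .curves import Family, extrinsic_loglik_vec, intrinsic_loglik_vec
from .simulate import CONDITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "FitSettings",
    "PosteriorEstimate",
    "PopulationPrior",
    "FitTrace",
    "condition_data",
    "fit_subject_condition",
    "update_population_prior",
    "fit_hierarchical",
    "estimates_to_frame",
]

LOG_2PI = math.log(2.0 * math.pi)

#: transformed-space dimensionality per family (curve params + one noise param)
FAMILY_DIM = {Family.LINEAR: 3, Family.SIGMOID: 4, Family.WEIBULL: 4}

#: transformed-space parameter names per family
FAMILY_PARAM_NAMES = {
    Family.LINEAR: ("m", "c", "log_noise"),
    Family.SIGMOID: ("bias", "log_c", "log_sigma", "log_noise"),
    Family.WEIBULL: ("log_A", "log_L", "log_S", "log_noise"),
}


def natural_params(family: Family, theta: np.ndarray) -> dict[str, float]:
    """Map a transformed parameter vector to natural-scale parameters."""
    family = Family(family)
    if family == Family.LINEAR:
        return {"m": theta[0], "c": theta[1], "noise": math.exp(theta[2])}
    if family == Family.SIGMOID:
        return {
            "bias": theta[0],
            "c": math.exp(theta[1]),
            "sigma": math.exp(theta[2]),
            "noise": math.exp(theta[3]),
        }
    return {
        "A": math.exp(theta[0]),
        "L": math.exp(theta[1]),
        "S": math.exp(theta[2]),
        "noise": math.exp(theta[3]),
    }


def _curve_y(family: Family, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    if family == Family.LINEAR:
        return theta[0] * x + theta[1]
    if family == Family.SIGMOID:
        c = math.exp(theta[1])
        sigma = math.exp(theta[2])
        return c * expit((x - theta[0]) / sigma)
    A = math.exp(theta[0])
    L = math.exp(theta[1])
    S = math.exp(theta[2])
    return A * (1.0 - np.exp2(-((x * L) ** S)))


def _bounds(family: Family, effort_cap: float) -> list[tuple[float, float]]:
    log_cap = math.log(effort_cap)
    log_noise = (math.log(0.2), math.log(40.0))
    if family == Family.LINEAR:
        return [(-500.0, 500.0), (-200.0, 200.0), log_noise]
    if family == Family.SIGMOID:
        return [(-3.0, 4.0), (math.log(0.5), log_cap), (math.log(1e-3), math.log(5.0)), log_noise]
    return [
        (math.log(0.5), log_cap),
        (math.log(0.05), math.log(50.0)),
        (math.log(0.05), math.log(20.0)),
        log_noise,
    ]


def initial_prior(
    family: Family, effort_cap: float = 70.0, sd: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Weakly informative round-1 prior in transformed space.

    Mid-range heuristics on the natural scale: bias 0.5, sigma 0.2,
    asymptote 0.75 * effort_cap, noise 5 presses; diagonal covariance with
    the given sd (broader for the linear family's untransformed slope and
    intercept).
    """
    family = Family(family)
    if family == Family.LINEAR:
        mean = np.array([30.0, 10.0, math.log(5.0)])
        sds = np.array([30.0, 20.0, sd])
    elif family == Family.SIGMOID:
        mean = np.array(
            [0.5, math.log(0.75 * effort_cap), math.log(0.2), math.log(5.0)]
        )
        sds = np.full(4, sd)
    else:
        mean = np.array(
            [math.log(0.75 * effort_cap), math.log(2.0), math.log(1.0), math.log(5.0)]
        )
        sds = np.full(4, sd)
    return mean, np.diag(sds**2)


@dataclass
class FitSettings:
    max_rounds: int = 16
    tol: float = 0.01
    n_starts: int = 4
    seed: int = 0
    effort_cap: float = 70.0
    hessian_step: float = 1e-4

    def validate(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.tol <= 0 or self.n_starts < 1:
            raise ValueError("tol must be > 0 and n_starts >= 1")


@dataclass
class PosteriorEstimate:
    subject_id: str
    condition: str
    family: Family
    mean: np.ndarray  # transformed space
    cov: np.ndarray
    log_evidence: float

    @property
    def natural(self) -> dict[str, float]:
        return natural_params(self.family, self.mean)


@dataclass
class PopulationPrior:
    """Per-condition Gaussian prior over transformed parameters."""

    family: Family
    mean: dict[str, np.ndarray]
    cov: dict[str, np.ndarray]
    round_index: int = 0


@dataclass
class FitTrace:
    group_log_evidence: list[float] = field(default_factory=list)
    converged: bool = False
    rounds_used: int = 0
    monotonicity_violations: list[int] = field(default_factory=list)


def condition_data(
    trials: pd.DataFrame, subject_id: str, condition: str
) -> dict[str, Any]:
    """Extract one subject's data arrays for one (control-valence) condition."""
    control, valence = condition.split("-")
    sub = trials[
        (trials["subject_id"] == subject_id)
        & (trials["control"] == control)
        & (trials["valence"] == valence)
    ]
    out: dict[str, Any] = {
        "control": control,
        "x": sub["outcome_norm"].to_numpy(dtype=float),
    }
    if control == "extrinsic":
        out["offered"] = sub["offered_effort"].to_numpy(dtype=float)
        out["accepted"] = sub["accepted"].astype(bool).to_numpy()
    else:
        out["reported"] = sub["reported_effort"].to_numpy(dtype=float)
    return out


def _neg_log_joint(
    theta: np.ndarray,
    family: Family,
    data: dict[str, Any],
    prior_mean: np.ndarray,
    prior_prec: np.ndarray,
    prior_logdet: float,
) -> float:
    y = _curve_y(family, theta, data["x"])
    noise = math.exp(theta[-1])
    if data["control"] == "extrinsic":
        ll = extrinsic_loglik_vec(y, data["offered"], data["accepted"], noise).sum()
    else:
        ll = intrinsic_loglik_vec(y, data["reported"], noise).sum()
    d = theta - prior_mean
    log_prior = -0.5 * (
        d @ prior_prec @ d + len(theta) * LOG_2PI + prior_logdet
    )
    val = -(ll + log_prior)
    return val if np.isfinite(val) else 1e12


def _fd_hessian(f, theta: np.ndarray, step: float) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    d = len(theta)
    h = step * np.maximum(1.0, np.abs(theta))
    H = np.zeros((d, d))
    f0 = f(theta)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / (h[i] ** 2)
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _spd(M: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to SPD by flooring its eigenvalues."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    return (V * np.maximum(w, floor)) @ V.T


def fit_subject_condition(
    data: dict[str, Any],
    family: Family,
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    settings: FitSettings | None = None,
    subject_id: str = "?",
    condition: str = "?",
) -> PosteriorEstimate:
    """MAP fit of one family to one subject-condition under a Gaussian prior.

    Quasi-Newton (L-BFGS-B) optimisation from ``n_starts`` deterministic
    starting points (prior mean plus seeded jitter); posterior covariance is
    the inverse Hessian of the negative log joint at the optimum;
    log evidence by the Laplace approximation.  With no trials the posterior
    equals the prior and the evidence is zero (no likelihood contribution).
    """
    settings = settings or FitSettings()
    settings.validate()
    family = Family(family)
    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_cov = _spd(np.asarray(prior_cov, dtype=float))

    if len(data["x"]) == 0:
        return PosteriorEstimate(
            subject_id, condition, family, prior_mean.copy(), prior_cov.copy(), 0.0
        )

    prior_prec = np.linalg.inv(prior_cov)
    sign, prior_logdet = np.linalg.slogdet(prior_cov)
    obj = lambda th: _neg_log_joint(
        th, family, data, prior_mean, prior_prec, prior_logdet
    )

    bounds = _bounds(family, settings.effort_cap)
    key = zlib.crc32(f"{subject_id}|{condition}|{family.value}".encode())
    rng = np.random.default_rng((settings.seed * 1000003 + key) % (2**31))
    prior_sd = np.sqrt(np.diag(prior_cov))
    starts = [prior_mean]
    for _ in range(settings.n_starts - 1):
        starts.append(prior_mean + rng.standard_normal(len(prior_mean)) * prior_sd)
    starts = [np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds]) for s in starts]

    best = None
    for s in starts:
        if not np.isfinite(obj(s)):
            continue
        res = minimize(obj, s, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"non-finite likelihood at all starts for subject {subject_id}, "
            f"condition {condition}, family {family.value}"
        )

    theta = np.asarray(best.x, dtype=float)
    H = _fd_hessian(obj, theta, settings.hessian_step)
    d = len(theta)
    sign, logdetH = np.linalg.slogdet(H)
    if sign <= 0 or not np.isfinite(logdetH):
        logger.warning(
            "singular Hessian for %s/%s/%s; falling back to prior covariance",
            subject_id,
            condition,
            family.value,
        )
        cov = prior_cov.copy()
        _, logdetH = np.linalg.slogdet(np.linalg.inv(_spd(cov)))
    else:
        cov = _spd(np.linalg.inv(_spd(H)))
    log_evidence = -best.fun + 0.5 * d * LOG_2PI - 0.5 * logdetH
    return PosteriorEstimate(subject_id, condition, family, theta, cov, float(log_evidence))


def update_population_prior(
    estimates: Iterable[PosteriorEstimate], round_index: int = 1
) -> PopulationPrior:
    """Empirical-Bayes prior update from subject-level posteriors.

    Per condition: prior mean is the mean of posterior means; prior
    covariance is the between-subject covariance of the means plus the mean
    within-subject posterior covariance, regularised to SPD.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates")
    family = Family(estimates[0].family)
    mean: dict[str, np.ndarray] = {}
    cov: dict[str, np.ndarray] = {}
    by_cond: dict[str, list[PosteriorEstimate]] = {}
    for e in estimates:
        by_cond.setdefault(e.condition, []).append(e)
    for cond, ests in by_cond.items():
        if len(ests) < 2:
            raise ValueError(f"need >= 2 estimates per condition, got {len(ests)} for {cond}")
        means = np.stack([e.mean for e in ests])
        mu = means.mean(axis=0)
        between = np.cov(means, rowvar=False, ddof=1)
        within = np.mean(np.stack([e.cov for e in ests]), axis=0)
        mean[cond] = mu
        cov[cond] = _spd(np.atleast_2d(between + within), floor=1e-6)
    return PopulationPrior(family=family, mean=mean, cov=cov, round_index=round_index)


def fit_hierarchical(
    trials: pd.DataFrame,
    family: Family,
    settings: FitSettings | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
    exclude_deterministic: bool = True,
) -> tuple[list[PosteriorEstimate], PopulationPrior, FitTrace]:
    """Fit one curve family to all subjects and conditions hierarchically.

    Alternates subject-level MAP fits (all conditions participate) with
    population-prior updates until the summed log evidence gains less than
    ``settings.tol`` nats or ``settings.max_rounds`` is reached.  Subjects
    answering identically on every extrinsic trial are excluded up front,
    mirroring the deterministic-choice exclusion rule.
    """
    from .simulate import find_deterministic_responders

    settings = settings or FitSettings()
    settings.validate()
    family = Family(family)

    subject_ids = sorted(trials["subject_id"].unique())
    if exclude_deterministic:
        bad = set(find_deterministic_responders(trials))
        if bad:
            logger.info("excluding %d deterministic responders: %s", len(bad), sorted(bad))
        subject_ids = [s for s in subject_ids if s not in bad]
    if len(subject_ids) < 2:
        raise ValueError("need >= 2 non-deterministic subjects")

    data_cache = {
        (sid, cond): condition_data(trials, sid, cond)
        for sid in subject_ids
        for cond in conditions
    }

    mean0, cov0 = initial_prior(family, settings.effort_cap)
    prior = PopulationPrior(
        family=family,
        mean={c: mean0.copy() for c in conditions},
        cov={c: cov0.copy() for c in conditions},
        round_index=0,
    )

    trace = FitTrace()
    estimates: list[PosteriorEstimate] = []
    prev = -np.inf
    for rnd in range(1, settings.max_rounds + 1):
        estimates = [
            fit_subject_condition(
                data_cache[(sid, cond)],
                family,
                prior.mean[cond],
                prior.cov[cond],
                settings,
                subject_id=sid,
                condition=cond,
            )
            for sid in subject_ids
            for cond in conditions
        ]
        total = float(sum(e.log_evidence for e in estimates))
        trace.group_log_evidence.append(total)
        trace.rounds_used = rnd
        if total < prev - settings.tol:
            logger.warning(
                "group log evidence decreased at round %d (%.3f -> %.3f)", rnd, prev, total
            )
            trace.monotonicity_violations.append(rnd)
        if abs(total - prev) < settings.tol:
            trace.converged = True
            break
        prev = total
        if rnd < settings.max_rounds:
            prior = update_population_prior(estimates, round_index=rnd)
    return estimates, prior, trace


def estimates_to_frame(estimates: Iterable[PosteriorEstimate]) -> pd.DataFrame:
    """One row per subject x condition x family, natural-scale parameters."""
    rows = []
    for e in estimates:
        row = {
            "subject_id": e.subject_id,
            "condition": e.condition,
            "family": Family(e.family).value,
            "log_evidence": e.log_evidence,
        }
        row.update(e.natural)
        rows.append(row)
    return pd.DataFrame(rows)
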