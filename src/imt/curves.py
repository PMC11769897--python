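"""Effort-by-outcome discount curves and their observation models.

Three psychometric families map a normalised outcome magnitude
``x in (0, 1]`` to the effort ``y`` (button presses) a participant is
willing to exert:

* linear:   ``y = m*x + c``
* sigmoid:  ``y = c / (1 + exp(-(x - bias) / sigma))``
* weibull:  ``y = A * (1 - 2**(-(x * L)**S))``

For the sigmoid, ``bias`` is the left-right shift -- the outcome threshold
at which effort initiation reaches half its ceiling, so a higher bias means
lower motivation (avolition) -- and ``sigma`` is the width: a higher sigma
gives a flatter curve, i.e. weaker adjustment of effort to outcome changes
(outcome insensitivity).  For the Weibull, ``L`` is the latency (the curve
reaches half its asymptote ``A`` at ``x = 1/L``) and ``S`` the abruptness.

The curve value at ``x`` is the subject's indifference effort, which makes
both IMT response types generative from one curve:

* extrinsic accept/reject follows a logistic choice rule with temperature
  ``tau``: ``P(accept) = 1 / (1 + exp(-(y(x) - offered) / tau))``;
* intrinsic self-set effort is the curve value perturbed by Gaussian report
  noise with standard deviation ``sigma_obs``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .task import Control, TrialSpec

__all__ = [
    "Family",
    "CurveParams",
    "ObservationParams",
    "eval_curve",
    "flatness_order",
    "loglik_extrinsic",
    "loglik_intrinsic",
]

LOG_2PI = math.log(2.0 * math.pi)


class Family(str, Enum):
    LINEAR = "linear"
    SIGMOID = "sigmoid"
    WEIBULL = "weibull"


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one discount-curve family.

    Field meaning depends on ``family``:

    ======== ==================================================
    linear   ``m`` gradient (presses / unit outcome), ``c`` intercept
    sigmoid  ``c`` asymptote (presses), ``bias`` shift, ``sigma`` width
    weibull  ``A`` asymptote (presses), ``L`` latency, ``S`` abruptness
    ======== ==================================================
    """

    family: Family
    m: float | None = None
    c: float | None = None
    bias: float | None = None
    sigma: float | None = None
    A: float | None = None
    L: float | None = None
    S: float | None = None
    effort_cap: float = 70.0

    def validate(self) -> None:
        fam = Family(self.family)
        if fam == Family.LINEAR:
            if self.m is None or self.c is None:
                raise ValueError("linear curve requires m and c")
        elif fam == Family.SIGMOID:
            if self.c is None or self.bias is None or self.sigma is None:
                raise ValueError("sigmoid curve requires c, bias and sigma")
            if self.sigma <= 0:
                raise ValueError("sigmoid sigma must be > 0")
            if not (0 < self.c <= self.effort_cap):
                raise ValueError(
                    f"sigmoid asymptote c={self.c} outside (0, effort_cap={self.effort_cap}]"
                )
        else:
            if self.A is None or self.L is None or self.S is None:
                raise ValueError("weibull curve requires A, L and S")
            if not (0 < self.A <= self.effort_cap):
                raise ValueError(
                    f"weibull asymptote A={self.A} outside (0, effort_cap={self.effort_cap}]"
                )
            if self.L <= 0:
                raise ValueError("weibull L must be > 0")
            if self.S <= 0:
                raise ValueError("weibull S must be > 0")

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        d["family"] = Family(self.family).value
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "CurveParams":
        d = json.loads(s)
        d["family"] = Family(d["family"])
        return cls(**d)


@dataclass(frozen=True)
class ObservationParams:
    """Noise parameters linking a curve to observed responses.

    ``choice_temperature`` (tau, presses) scales the logistic accept/reject
    noise on extrinsic trials; ``intrinsic_sd`` (sigma_obs, presses) is the
    Gaussian report noise on intrinsic trials.  Both strictly positive.
    """

    choice_temperature: float = 5.0
    intrinsic_sd: float = 5.0

    def validate(self) -> None:
        if self.choice_temperature <= 0:
            raise ValueError("choice_temperature must be > 0")
        if self.intrinsic_sd <= 0:
            raise ValueError("intrinsic_sd must be > 0")


def eval_curve(params: CurveParams, x) -> np.ndarray | float:
    """Predicted effort y(x) in presses; vectorised over ``x``.

    The output is *not* clamped to [0, effort_cap]; clamping belongs to the
    observation stage only.
    """
    params.validate()
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("outcome x must be >= 0")
    fam = Family(params.family)
    if fam == Family.LINEAR:
        y = params.m * x + params.c
    elif fam == Family.SIGMOID:
        from scipy.special import expit

        y = params.c * expit((x - params.bias) / params.sigma)
    else:
        y = params.A * (1.0 - np.exp2(-((x * params.L) ** params.S)))
    return float(y) if y.ndim == 0 else y


def flatness_order(
    params_a: CurveParams,
    params_b: CurveParams,
    x_lo: float,
    x_hi: float,
) -> str:
    """Which of two sigmoid parameter sets is flatter over [x_lo, x_hi].

    Both curves must share ``c`` and ``bias``; the set with the larger sigma
    spans the smaller effort range, i.e. is flatter.  Returns ``"a"``,
    ``"b"`` or ``"tie"``.
    """
    for p in (params_a, params_b):
        if Family(p.family) != Family.SIGMOID:
            raise ValueError("flatness_order is defined for sigmoid curves only")
        p.validate()
    if params_a.c != params_b.c or params_a.bias != params_b.bias:
        raise ValueError("curves must share c and bias")
    if not x_lo < x_hi:
        raise ValueError("x_lo must be < x_hi")
    range_a = abs(eval_curve(params_a, x_hi) - eval_curve(params_a, x_lo))
    range_b = abs(eval_curve(params_b, x_hi) - eval_curve(params_b, x_lo))
    if math.isclose(range_a, range_b, rel_tol=1e-12, abs_tol=1e-12):
        return "tie"
    return "a" if range_a < range_b else "b"


def _accept_logp(y: float, offered: float, tau: float) -> tuple[float, float]:
    """(log P(accept), log P(reject)) via numerically stable log-logistic."""
    z = (y - offered) / tau
    # log(sigmoid(z)) = -log1p(exp(-z))
    if z >= 0:
        log_p = -math.log1p(math.exp(-z))
        log_q = -z - math.log1p(math.exp(-z))
    else:
        log_p = z - math.log1p(math.exp(z))
        log_q = -math.log1p(math.exp(z))
    return log_p, log_q


def loglik_extrinsic(
    params: CurveParams,
    obs: ObservationParams,
    trial: TrialSpec,
    accepted: bool,
) -> float:
    """Log-likelihood of one extrinsic accept/reject response."""
    if trial.control != Control.EXTRINSIC:
        raise ValueError("loglik_extrinsic requires an extrinsic trial")
    obs.validate()
    y = float(eval_curve(params, trial.outcome_norm))
    log_p, log_q = _accept_logp(y, float(trial.offered_effort), obs.choice_temperature)
    return log_p if accepted else log_q


def loglik_intrinsic(
    params: CurveParams,
    obs: ObservationParams,
    trial: TrialSpec,
    reported_effort: float,
) -> float:
    """Log-likelihood of one intrinsic self-set effort report."""
    if trial.control != Control.INTRINSIC:
        raise ValueError("loglik_intrinsic requires an intrinsic trial")
    obs.validate()
    if not (0 <= reported_effort <= params.effort_cap):
        raise ValueError(
            f"reported_effort {reported_effort} outside [0, {params.effort_cap}]"
        )
    y = float(eval_curve(params, trial.outcome_norm))
    sd = obs.intrinsic_sd
    z = (reported_effort - y) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * LOG_2PI


# -- vectorised likelihood kernels used by the fitting loop -------------------


def extrinsic_loglik_vec(
    y: np.ndarray, offered: np.ndarray, accepted: np.ndarray, tau: float
) -> np.ndarray:
    """Per-trial log-likelihood of accept/reject responses (vectorised)."""
    z = (y - offered) / tau
    # log sigmoid(z) and log sigmoid(-z), stable for large |z|
    log_p = -np.logaddexp(0.0, -z)
    log_q = -np.logaddexp(0.0, z)
    return np.where(accepted, log_p, log_q)


def intrinsic_loglik_vec(
    y: np.ndarray, reported: np.ndarray, sd: float
) -> np.ndarray:
    """Per-trial Gaussian log-likelihood of self-set effort reports."""
    z = (reported - y) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * LOG_2PI
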