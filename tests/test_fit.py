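import itertools
import math

import numpy as np
import pandas as pd
import pytest

from imt.curves import Family
from imt.fit import (
    FitSettings,
    PosteriorEstimate,
    condition_data,
    estimates_to_frame,
    fit_hierarchical,
    fit_subject_condition,
    initial_prior,
    natural_params,
    update_population_prior,
    _neg_log_joint,
)
from imt.simulate import default_cohort_spec, generate_cohort
from imt.task import ScheduleConfig
from tests.conftest import attach_truth


def intrinsic_data(bias=0.5, sigma=0.12, c=52.5, sd=0.5, n=500, seed=0):
    """Dense low-noise intrinsic-condition data from a known sigmoid."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.05, 1.0, n)
    y = c / (1 + np.exp(-(x - bias) / sigma))
    return {
        "control": "intrinsic",
        "x": x,
        "reported": y + sd * rng.standard_normal(n),
    }


class TestFitSubjectCondition:
    def test_empty_data_returns_prior(self):
        mean, cov = initial_prior(Family.SIGMOID)
        est = fit_subject_condition(
            {"control": "intrinsic", "x": np.array([])}, Family.SIGMOID, mean, cov
        )
        assert np.allclose(est.mean, mean)
        assert np.allclose(est.cov, cov)
        assert est.log_evidence == 0.0

    def test_recovers_known_sigmoid(self):
        """Low-noise data pin the bias to within +-0.05 of truth, and the MAP
        beats every point of a grid-search maximum-likelihood oracle."""
        data = intrinsic_data(bias=0.5, n=500)
        mean, cov = initial_prior(Family.SIGMOID)
        est = fit_subject_condition(data, Family.SIGMOID, mean, cov)
        nat = est.natural
        assert nat["bias"] == pytest.approx(0.5, abs=0.05)

        # grid oracle over (bias, sigma, c) at the fitted noise level
        prior_prec = np.linalg.inv(cov)
        _, prior_logdet = np.linalg.slogdet(cov)
        obj = lambda th: _neg_log_joint(
            th, Family.SIGMOID, data, mean, prior_prec, prior_logdet
        )
        log_noise = est.mean[-1]
        best_grid = math.inf
        best_theta = None
        for b, lc, ls in itertools.product(
            np.linspace(0.2, 0.8, 13),
            np.log(np.linspace(30, 70, 9)),
            np.log(np.linspace(0.05, 0.4, 8)),
        ):
            v = obj(np.array([b, lc, ls, log_noise]))
            if v < best_grid:
                best_grid, best_theta = v, (b, lc, ls)
        assert obj(est.mean) <= best_grid + 1e-6
        assert abs(nat["bias"] - best_theta[0]) <= 0.05 + 1e-9

    def test_dominating_prior_pins_posterior(self):
        data = intrinsic_data(bias=0.7, n=50)
        mean, _ = initial_prior(Family.SIGMOID)
        tiny = np.eye(4) * 1e-8
        est = fit_subject_condition(data, Family.SIGMOID, mean, tiny)
        assert np.allclose(est.mean, mean, atol=1e-3)

    def test_posterior_covariance_spd_and_evidence_finite(self):
        data = intrinsic_data(n=60, seed=3)
        mean, cov = initial_prior(Family.SIGMOID)
        est = fit_subject_condition(data, Family.SIGMOID, mean, cov)
        w = np.linalg.eigvalsh(est.cov)
        assert (w > 0).all()
        assert np.isfinite(est.log_evidence)

    def test_reparameterization_consistency(self):
        """MAP through the log-transform agrees with direct constrained
        optimisation on the natural scale for an easy instance."""
        from scipy.optimize import minimize

        data = intrinsic_data(bias=0.45, n=400, seed=5)
        mean, cov = initial_prior(Family.SIGMOID, sd=5.0)  # near-flat prior
        est = fit_subject_condition(data, Family.SIGMOID, mean, cov)
        nat = est.natural

        def nll_natural(p):
            b, c, s, sd = p
            y = c / (1 + np.exp(-(data["x"] - b) / s))
            z = (data["reported"] - y) / sd
            return float(np.sum(0.5 * z * z + math.log(sd) + 0.5 * math.log(2 * math.pi)))

        res = minimize(
            nll_natural,
            [0.5, 50.0, 0.15, 1.0],
            method="L-BFGS-B",
            bounds=[(0.0, 1.0), (5, 70), (0.01, 2), (0.05, 10)],
        )
        assert nat["bias"] == pytest.approx(res.x[0], abs=0.02)
        assert nat["c"] == pytest.approx(res.x[1], rel=0.05)
        assert nat["sigma"] == pytest.approx(res.x[2], rel=0.15)


class TestPopulationPrior:
    def make_estimate(self, mean, cov, cond="intrinsic-win"):
        return PosteriorEstimate("S", cond, Family.SIGMOID, np.asarray(mean, float), np.asarray(cov, float), 0.0)

    def test_identical_estimates_degenerate(self):
        e = [self.make_estimate([1.0, 2.0], np.eye(2) * 0.1) for _ in range(5)]
        prior = update_population_prior(e)
        assert np.allclose(prior.mean["intrinsic-win"], [1.0, 2.0])

    def test_symmetric_pair_mean_zero(self):
        e = [
            self.make_estimate([1.0, -2.0], np.eye(2)),
            self.make_estimate([-1.0, 2.0], np.eye(2)),
        ]
        prior = update_population_prior(e)
        assert np.allclose(prior.mean["intrinsic-win"], [0.0, 0.0])

    def test_matches_two_pass_loop_oracle(self):
        rng = np.random.default_rng(7)
        means = rng.standard_normal((50, 3))
        covs = []
        for _ in range(50):
            a = rng.standard_normal((3, 3)) * 0.2
            covs.append(a @ a.T + np.eye(3) * 0.1)
        ests = [self.make_estimate(m, c) for m, c in zip(means, covs)]
        prior = update_population_prior(ests)
        # explicit loop oracle
        mu = sum(means) / 50
        between = np.zeros((3, 3))
        for m in means:
            d = (m - mu)[:, None]
            between += d @ d.T
        between /= 49
        within = sum(covs) / 50
        assert np.allclose(prior.mean["intrinsic-win"], mu, atol=1e-12)
        assert np.allclose(prior.cov["intrinsic-win"], between + within, atol=1e-9)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            update_population_prior([self.make_estimate([0.0], [[1.0]])])


class TestHierarchicalLoop:
    def test_single_round_equals_independent_fits(self):
        cohort = generate_cohort(default_cohort_spec(3, 2, 2), seed=21)
        settings = FitSettings(max_rounds=1, seed=21)
        estimates, prior, trace = fit_hierarchical(
            cohort.trials, Family.SIGMOID, settings
        )
        assert trace.rounds_used == 1
        mean0, cov0 = initial_prior(Family.SIGMOID)
        for est in estimates[:4]:
            data = condition_data(cohort.trials, est.subject_id, est.condition)
            solo = fit_subject_condition(
                data, Family.SIGMOID, mean0, cov0, settings,
                subject_id=est.subject_id, condition=est.condition,
            )
            assert np.allclose(solo.mean, est.mean)
            assert solo.log_evidence == pytest.approx(est.log_evidence)

    def test_deterministic_responders_excluded(self):
        cohort = generate_cohort(default_cohort_spec(3, 2, 2), seed=2)
        trials = cohort.trials.copy()
        sid = trials["subject_id"].iloc[0]
        mask = (trials["subject_id"] == sid) & (trials["control"] == "extrinsic")
        trials.loc[mask, "accepted"] = True
        estimates, _, _ = fit_hierarchical(
            trials, Family.SIGMOID, FitSettings(max_rounds=1)
        )
        assert sid not in {e.subject_id for e in estimates}

    def test_recovery_improves_with_trial_count(self):
        """Bias recovery (averaged over seeds) improves as sessions lengthen
        from a quarter to the full 228 trials."""
        sizes = [57, 114, 228]
        mean_r = []
        for n_trials in sizes:
            rs = []
            for seed in range(5):
                cohort = generate_cohort(
                    default_cohort_spec(10, 1, 1)[:1],
                    seed=100 + seed,
                    schedule_config=ScheduleConfig(n_trials=n_trials, seed=seed),
                )
                est, _, _ = fit_hierarchical(
                    cohort.trials,
                    Family.SIGMOID,
                    FitSettings(max_rounds=2, seed=seed),
                )
                df = attach_truth(estimates_to_frame(est), cohort.truth)
                rs.append(np.corrcoef(df["bias"], df["true_bias"])[0, 1])
            mean_r.append(np.mean(rs))
        assert mean_r[0] <= mean_r[1] + 0.02
        assert mean_r[1] <= mean_r[2] + 0.02

    def test_estimates_frame_schema(self, recovery_frame):
        assert {"subject_id", "condition", "family", "log_evidence", "bias", "sigma", "c", "noise"} <= set(recovery_frame.columns)
        assert recovery_frame["log_evidence"].notna().all()


class TestNaturalParams:
    def test_transforms_round_trip(self):
        theta = np.array([0.4, math.log(50.0), math.log(0.1), math.log(4.0)])
        nat = natural_params(Family.SIGMOID, theta)
        assert nat == pytest.approx(
            {"bias": 0.4, "c": 50.0, "sigma": 0.1, "noise": 4.0}
        )
        lin = natural_params(Family.LINEAR, np.array([2.0, -1.0, 0.0]))
        assert lin == pytest.approx({"m": 2.0, "c": -1.0, "noise": 1.0})
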