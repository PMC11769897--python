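"""Internal consistency and test-retest stability.

Cronbach's alpha over the four condition "items" for bias and sigma, and a
simulated retest: ten subjects repeat the task (same true parameters, fresh
response noise), both sessions are refit, and per-condition paired t tests
ask whether the recovered bias drifts between sessions.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from imt.curves import CurveParams, Family, ObservationParams
from imt.fit import FitSettings, estimates_to_frame, fit_hierarchical
from imt.io import read_dataset
from imt.simulate import simulate_responses
from imt.stats import cronbach_alpha, paired_ttest
from imt.task import ScheduleConfig, build_schedule

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--cohort", type=str, default="results/cohort")
parser.add_argument("--n-retest", type=int, default=10)
args = parser.parse_args()

cohort_dir = Path(args.cohort)
ds = read_dataset(cohort_dir / "subjects.csv", cohort_dir / "trials.csv")
est = pd.read_csv(cohort_dir / "estimates.csv")
sig = est[est["family"] == "sigmoid"]

out = {}
for measure in ("bias", "sigma"):
    wide = sig.pivot(index="subject_id", columns="condition", values=measure)
    out[f"cronbach_alpha_{measure}"] = cronbach_alpha(wide.to_numpy())
    print(f"Cronbach's alpha ({measure}, 4 items): {out[f'cronbach_alpha_{measure}']:.2f}")

# --- simulated retest -------------------------------------------------------
with open(cohort_dir / "truth.json") as fh:
    truth = json.load(fh)["subjects"]
retest_ids = sorted(truth)[: args.n_retest]
schedule = build_schedule(ScheduleConfig(seed=args.seed + 1))
rng = np.random.default_rng(args.seed + 2)

frames = []
for session in (1, 2):
    for sid in retest_ids:
        t = truth[sid]
        params = {
            cond: CurveParams(family=Family.SIGMOID, **p) for cond, p in t["params"].items()
        }
        obs = ObservationParams(choice_temperature=t["tau"], intrinsic_sd=t["sigma_obs"])
        resp = simulate_responses(params, obs, schedule, rng)
        resp.insert(0, "subject_id", f"{sid}-s{session}")
        frames.append(resp)

retest_trials = pd.concat(frames, ignore_index=True)
fits, _, _ = fit_hierarchical(
    retest_trials, "sigmoid", FitSettings(max_rounds=2, seed=args.seed)
)
fit_df = estimates_to_frame(fits)
fit_df["session"] = fit_df["subject_id"].str[-1].astype(int)
fit_df["base_id"] = fit_df["subject_id"].str[:-3]

print(f"\ntest-retest (n = {len(retest_ids)} simulated repeat subjects):")
out["retest"] = {}
for cond, sub in fit_df.groupby("condition"):
    s1 = sub[sub.session == 1].sort_values("base_id")["bias"].to_numpy()
    s2 = sub[sub.session == 2].sort_values("base_id")["bias"].to_numpy()
    res = paired_ttest(s1, s2)
    out["retest"][cond] = res
    print(f"  {cond:15s} paired t({res['df']}) = {res['t']:.2f}, p = {res['p']:.2f}")

with open(cohort_dir / "reliability.json", "w") as fh:
    json.dump(out, fh, indent=1)
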