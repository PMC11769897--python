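"""Group and symptom statistics on the winning (sigmoid) parameters.

Repeated-measures ANOVAs on bias, sigma and reaction time (control x
valence within, group between), Tukey post-hoc contrasts, covariate-
adjusted partial correlations between symptom scales and per-condition
parameters (scale-wise Bonferroni at p < 0.0125), and dependent-correlation
Z tests contrasting anticipatory vs consummatory anhedonia.
"""

import argparse
from pathlib import Path

import pandas as pd

from imt.io import read_dataset
from imt.stats import (
    correlation_battery,
    dependent_corr_diff,
    format_anova_report,
    parameter_long_table,
    partial_corr,
    rm_anova,
    rt_long_table,
    tukey_posthoc,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=str, default="results/cohort")
args = parser.parse_args()

cohort_dir = Path(args.cohort)
ds = read_dataset(cohort_dir / "subjects.csv", cohort_dir / "trials.csv")
est = pd.read_csv(cohort_dir / "estimates.csv")
sig = est[est["family"] == "sigmoid"]

anovas, posthocs = [], []
for measure in ("bias", "sigma"):
    table = parameter_long_table(sig, ds.subjects, measure)
    a = rm_anova(table, measure, within=["control", "valence"], between="group")
    a.insert(0, "dv", measure)
    anovas.append(a)
    print(format_anova_report(a, measure) + "\n")
    ph = tukey_posthoc(table, dv=measure, factor="group")
    ph.insert(0, "dv", measure)
    posthocs.append(ph)

rt = rt_long_table(ds.trials, ds.subjects)
a_rt = rm_anova(rt, "reaction_time", within=["control", "valence"], between="group")
a_rt.insert(0, "dv", "reaction_time")
anovas.append(a_rt)
print(format_anova_report(a_rt, "reaction_time") + "\n")

pd.concat(anovas, ignore_index=True).to_csv(cohort_dir / "anova.csv", index=False)
pd.concat(posthocs, ignore_index=True).to_csv(cohort_dir / "posthoc.csv", index=False)

scales = [
    "teps_anticipatory",
    "teps_consummatory",
    "sticsa_cognitive",
    "sticsa_somatic",
    "pss",
    "qids",
]
corrs = []
for measure in ("bias", "sigma"):
    corrs.append(correlation_battery(sig, ds.subjects, measure, scales))
corr = pd.concat(corrs, ignore_index=True)
corr.to_csv(cohort_dir / "correlations.csv", index=False)
sig_rows = corr[corr["bonferroni_pass"]]
print(f"partial correlations passing scale-wise Bonferroni (p < 0.0125): {len(sig_rows)}")
for _, r in sig_rows.iterrows():
    print(f"  {r['measure']} {r['condition']} x {r['scale']}: r = {r['r']:.3f}, p = {r['p']:.4f}")

# dependent-correlation contrast: does extrinsic-win bias correlate more
# strongly with anticipatory than consummatory anhedonia?
wide = sig[sig["condition"] == "extrinsic-win"].set_index("subject_id")["bias"]
subj = ds.subjects.set_index("subject_id").loc[wide.index]
cov = pd.DataFrame(
    {
        "age": subj["age"],
        "sex": (subj["sex"] == "F").astype(float),
        "med": subj["medication"].astype(float),
    }
)
r_ant = partial_corr(wide, subj["teps_anticipatory"], cov)["r"]
r_con = partial_corr(wide, subj["teps_consummatory"], cov)["r"]
r_scales = subj["teps_anticipatory"].corr(subj["teps_consummatory"])
z = dependent_corr_diff(r_ant, r_con, r_scales, n=len(wide))
print(
    f"\nextrinsic-win bias: anticipatory r = {r_ant:.3f} vs consummatory r = {r_con:.3f}; "
    f"difference Z = {z['Z']:.2f}, one-sided p = {z['p']:.3f}"
)
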