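"""Generate the synthetic study cohort.

Builds a three-group cohort (HC/MDD/ANX) with the task's 228-trial design
and writes subjects.csv, trials.csv and the true-parameter manifest under
results/cohort/.  Group sizes default to a 40-subject scaled cohort so the
full analysis sequence runs in minutes; pass --full for the study-sized
74/63/44 cohort.
"""

import argparse
from pathlib import Path

from imt.simulate import default_cohort_spec, generate_cohort

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--full", action="store_true", help="74/63/44 study-sized cohort")
parser.add_argument("--outdir", type=str, default="results/cohort")
args = parser.parse_args()

sizes = (74, 63, 44) if args.full else (20, 12, 8)
cohort = generate_cohort(default_cohort_spec(*sizes), seed=args.seed)
outdir = Path(args.outdir)
cohort.write(outdir)

print(f"wrote {len(cohort.subjects)} subjects x {len(cohort.schedule)} trials to {outdir}/")
print(cohort.subjects["group"].value_counts().to_string())
det = cohort.truth["deterministic_responders"]
print(f"deterministic responders: {len(det)}")
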