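# File schemas

All tabular outputs are plain CSV (comma-separated, header row, UTF-8);
structured outputs are JSON; configuration is YAML.

## subjects.csv

| column | type | meaning |
|---|---|---|
| subject_id | str | unique id (`S0000`, ...) |
| group | str | `HC`, `MDD` or `ANX` |
| age | float | years |
| sex | str | `F` / `M` |
| medication | bool | psychoactive medication flag |
| teps_anticipatory | float | anticipatory pleasure (10–60; lower = worse anhedonia) |
| teps_consummatory | float | consummatory pleasure (8–48) |
| sticsa_cognitive | float | cognitive anxiety (10–40) |
| sticsa_somatic | float | somatic anxiety (11–44) |
| pss | float | perceived stress (0–40) |
| qids | float | depression severity (0–27) |

## trials.csv

| column | type | meaning |
|---|---|---|
| subject_id | str | joins subjects.csv |
| trial_index | int | position in the session |
| control | str | `extrinsic` / `intrinsic` |
| valence | str | `win` / `loss` |
| outcome_type | str | `money` / `social` |
| outcome_magnitude | float | native scale ($ or points) |
| outcome_norm | float | magnitude / scale maximum, in (0, 1] |
| offered_effort | int or empty | presses offered (extrinsic only) |
| executes_effort | bool | trial leads to actual effort performance |
| accepted | bool or empty | extrinsic accept/reject response |
| reported_effort | float or empty | intrinsic self-set presses |
| reaction_time | float | seconds |

## estimates.csv

One row per subject × condition × family: `subject_id`, `condition`
(`extrinsic-win` etc.), `family`, `log_evidence` (nats, Laplace), then
natural-scale parameters (`bias`, `sigma`, `c` for sigmoid; `m`, `c` for
linear; `A`, `L`, `S` for Weibull) and `noise` (τ or σ_obs in presses).

## Other artifacts

* `truth.json` — generator manifest: per-subject true parameters, τ,
  σ_obs, group; list of deterministic responders.
* `trace.json` — per-family fit trace: per-round group log evidence,
  convergence flag, rounds used.
* `bms.json` / `bms_summary.csv` — Dirichlet α, expected frequencies, EP,
  BOR, PXP / per-subject attribution probabilities and best family.
* `anova.csv` (`dv`, `effect`, `F`, `df1`, `df2`, `p`), `posthoc.csv`
  (`dv`, `contrast`, `difference`, `q`, `p_adj`), `correlations.csv`
  (`scale`, `condition`, `measure`, `r`, `p`, `n`, `bonferroni_alpha`,
  `bonferroni_pass`), `reliability.json`, `report.txt`.
* `manifest.json` — run config, config hash, seed, package versions.
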