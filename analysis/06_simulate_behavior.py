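#!/usr/bin/env python
"""Simulate the 4-mouse T-maze cohort and summarise its behavior.

Injects the published per-mouse stimulation deltas into the generative
model, summarises accuracy per (mouse, condition, label), breaks trials
into the four outcome-history types, and runs the Friedman test across
types.  Writes the trial table and summary CSVs.
"""
import argparse
from pathlib import Path

import numpy as np

from thetaloop.behavior_sim import BehaviorParams, simulate_cohort
from thetaloop.behavior_stats import (TABLE1_ACCURACY, classify_trial_types,
                                      friedman_test, summarize_accuracy)
from thetaloop.io import write_json, write_trials

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path, default=Path("results/behavior"))
args = parser.parse_args()

# per-mouse stimulation effects = printed accuracy deltas vs baseline
effects = {}
for (mouse, cond), row in TABLE1_ACCURACY.items():
    eff = effects.setdefault(mouse, {})
    eff[cond] = {"baseline": 0.0,
                 "peak": row["peak"] - row["baseline"],
                 "trough": row["trough"] - row["baseline"]}
params = BehaviorParams(seed=args.seed)
cohort = simulate_cohort(params, effects_by_mouse=effects, seed=args.seed)
args.outdir.mkdir(parents=True, exist_ok=True)
write_trials(cohort, args.outdir / "trials.csv")

summary = summarize_accuracy(cohort)
summary.table.to_csv(args.outdir / "accuracy.csv", index=False)
print("group mean accuracy (%):")
for (cond, stim), value in sorted(summary.group_means().items()):
    print(f"  {cond:10s} {stim:9s} {value:5.1f}")

types = classify_trial_types(cohort)
types.table.to_csv(args.outdir / "trial_types.csv", index=False)
types.deltas.to_csv(args.outdir / "trial_type_deltas.csv", index=False)

friedman = {}
for cond in ("retrieval", "encoding"):
    tab = types.table
    sub = tab[(tab.condition == cond) & (tab.stim == "baseline")]
    # subjects x trial types needs per-mouse accuracies: recompute per mouse
    rows = []
    frame = cohort[cohort["trial_type"].notna() & (cohort.condition == cond)
                   & (cohort.stim == "baseline")]
    for mouse, grp in frame.groupby("mouse_id"):
        rows.append(grp.groupby("trial_type")["correct"].mean().reindex(
            sorted(frame["trial_type"].unique())).to_numpy())
    chi2, df, p = friedman_test(np.vstack(rows))
    friedman[cond] = {"chi2": chi2, "df": df, "p": p}
    print(f"Friedman across trial types, {cond}: chi2={chi2:.1f}, p={p:.3f}")
write_json(friedman, args.outdir / "friedman.json")
print("reference trial-type effects: chi2=8.4 p=0.038 (retrieval), "
      "chi2=8.1 p=0.044 (encoding)")
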