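#!/usr/bin/env python
"""Behavioural metrics on simulated Go/No-Go sessions.

A staged learner ramps its per-trial correct-response probability across
blocks; blockwise accuracy, trials-to-criterion (80%), and per-background
lick preference indices are computed.  Writes
results/behaviour_learning_curve.csv and results/behaviour_lick_preference.csv.

Findings to expect: the learning curve crosses the 80% criterion at the end
of the block where the underlying probability does; with few licks on
unrewarded trials the lick preference index approaches 1 for every
background.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from obmix.behaviour import learning_curve, lick_preference_index
from obmix.synthetic import simulate_behaviour


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    trials = []
    for i, p in enumerate((0.55, 0.65, 0.75, 0.9, 0.95, 0.95)):
        trials.extend(simulate_behaviour(50, p, 6.0, 0.3, seed=args.seed + i))
    lc = learning_curve(trials)
    curve = pd.DataFrame(
        {"block": np.arange(1, len(lc["block_accuracy"]) + 1),
         "accuracy": lc["block_accuracy"]}
    )
    curve.to_csv(args.out / "behaviour_learning_curve.csv", index=False)
    print("blockwise accuracy:")
    print(curve.round(3).to_string(index=False))
    print(f"trials to 80% criterion: {lc['trials_to_criterion']}\n")

    expert = simulate_behaviour(600, 0.95, 6.0, 0.2, seed=args.seed + 10)
    idx = lick_preference_index(expert)
    idx.to_csv(args.out / "behaviour_lick_preference.csv", index=False)
    print("lick preference index per background:")
    print(idx.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
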