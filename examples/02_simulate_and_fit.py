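"""Simulate one observer's 2IFC blocks and recover the parameters.

An optimally-averaging observer with single-cue noises sigma_D = 0.2 and
sigma_S = 0.3 should show a fused bimodal noise of sqrt(product/sum) ~ 0.166.
We simulate the three condition blocks, run the two-stage fit (shared lapse,
then per-condition slope) and compare fitted to generative noise.
"""

import numpy as np
import pandas as pd

from cuecombine import (ConditionSpec, ObserverProfile, fit_trial_table,
                        optimal_sigma, simulate_trials)

S2 = np.sqrt(2.0)
obs = ObserverProfile(sigma_D=0.2, sigma_S=0.3, lapse=0.04, strategy="optimal")

frames = [
    simulate_trials(obs, ConditionSpec(("D",)), n_reps=12, seed=1,
                    condition_label="D"),
    simulate_trials(obs, ConditionSpec(("S",)), n_reps=12, seed=2,
                    condition_label="S"),
    simulate_trials(obs, ConditionSpec(("D", "S")), n_reps=12, seed=3,
                    condition_label="DS"),
]
trials = pd.concat(frames, ignore_index=True)
print(f"simulated {len(trials)} trials "
      f"({int(trials['easy'].sum())} flagged 'easy', excluded from fits)\n")

fits = fit_trial_table(trials)
fits["sigma"] = 1.0 / (fits["beta"] * S2)
truth = {"D": 0.2, "S": 0.3, "DS": optimal_sigma(0.2, 0.3).sigma_opt}
print("condition   fitted sigma   generative sigma")
for _, row in fits.iterrows():
    print(f"  {row['condition']:<8}  {row['sigma']:.3f}          "
          f"{truth[row['condition']]:.3f}")
print(f"\nshared lapse estimate: {fits['lambda'].iloc[0]:.3f} (true 0.040)")
print("The DS noise sits below both single cues: the signature of cue "
      "combination that the marker analyses quantify.")
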