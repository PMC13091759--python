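"""Simulation-based power for detecting a group combination benefit.

Every cell simulates complete experiments end to end: binomial 2IFC data for
best, worst and optimally-combined conditions, psychometric fits, and the
group two-tailed Wilcoxon test of combined vs best single-cue noise.  200
simulations per cell keep this example quick; the headline analyses use 1,000.
"""

from cuecombine import power_grid

table = power_grid(sigma_best_values=[0.2], noise_ratios=[1.5, 2.0],
                   ns=[15, 30], n_sims=200, seed=0)
cols = ["n_participants", "noise_ratio", "power", "rejection_rate", "mc_se"]
print(table[cols].to_string(index=False, float_format="%.3f"))
print("""
Power falls as the single-cue noise ratio grows (the combined estimate can
beat the best cue by less) and rises with the number of participants; mc_se
is the binomial Monte-Carlo error of each power estimate.""")
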