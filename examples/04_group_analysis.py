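"""Group-level inference on a messy cohort: exclusions and hypothesis tests.

The 'messy_cohort' fixture plants one observer with unusable disparity noise,
one chronic lapser and one inverse audio mapper; the exclusion rules should
catch all three before the marker tests run.
"""

from cuecombine import (analyze_metrics, fit_trial_table, make_fixture,
                        metrics_from_fits, render_report)
from cuecombine.group import detect_inverse_mapping

trials, info = make_fixture("messy_cohort", n_participants=8,
                            n_trials_per_condition=84)
print("planted problems:", info["tweaks"], "\n")

fits = fit_trial_table(trials)
metrics = metrics_from_fits(fits)
inverse = detect_inverse_mapping(trials)
results = analyze_metrics(metrics, fits, inverse_mapping_participants=inverse)

print(render_report(results))
print("Every planted problem should appear under 'Exclusions' with the rule "
      "that caught it; the marker tests below run on the remaining observers.")
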