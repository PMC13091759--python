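# cuecombine

Simulation and analysis of two-interval forced-choice (2IFC) cue-combination
experiments in depth perception.

When two sensory cues signal the same depth — say binocular disparity and
retinal size, or disparity and a newly learned pitch-to-depth mapping — an
ideal observer averages them weighted by their reliabilities.  The statistical
signatures of that process are measurable from psychophysics: the bimodal
discrimination noise should drop below the best single cue, cue weights should
track reliability when one cue is perturbed, and reversing a learned mapping
should cost precision.  `cuecombine` provides the full tool chain for studying
these questions without touching a display: parameterised generative
observers, Bayesian psychometric fitting, integration markers, group-level
inference, mixed-model repeatability, and simulation-based power analysis.

It is written for psychophysicists and computational-perception researchers
who want to (a) plan such studies (power, design), (b) validate analysis
pipelines against observers with known ground truth, and (c) analyse tidy
per-trial response tables from real experiments.

## The model

Responses in a 2IFC depth discrimination with reference at 0 follow

```
psi(x; alpha, beta, lambda) = lambda + (1 - lambda) * Phi(beta * (x - alpha))
```

with PSE `alpha`, slope `beta`, lapse rate `lambda`.  Because the judgment
compares two noisy interval estimates, the single-estimate sensory noise is
`sigma = 1 / (beta * sqrt(2))` and the just-noticeable difference is
`JND = 1 / beta`.  The reliability-weighted ideal observer predicts

```
sigma_12_opt = sqrt(s1^2 s2^2 / (s1^2 + s2^2))          (combined noise)
w_1          = s2^2 / (s1^2 + s2^2)                     (weight of cue 1)
```

and a cue conflict `delta` planted in the reference shifts the PSE by
`(1 - w_1) * delta`, so empirical weights are read out as
`w_emp = 1 - mu_PSE / delta`.  Per participant and cue pair the package
reports three markers:

* `CI = min(single-cue sigmas) - bimodal sigma` (combination benefit),
* `RI = w_emp(normal) - w_emp(noisy disparity)` (re-weighting),
* `IS = incongruent sigma - congruent sigma` (incongruence sensitivity).

Fitting is Bayesian on dense grids with uniform priors (`beta` on (0, 200],
`alpha` on [-1, 1] where free, `lambda` on [0, 0.2]) in two stages: a shared
lapse per participant x session across conditions, then per-condition
slope/PSE with the lapse fixed — which measurably reduces bias and imprecision
in `beta`.

## A worked example

```python
import numpy as np, pandas as pd
from cuecombine import (ConditionSpec, ObserverProfile, fit_trial_table,
                        optimal_sigma, simulate_trials)

obs = ObserverProfile(sigma_D=0.2, sigma_S=0.3, lapse=0.04, strategy="optimal")
trials = pd.concat([
    simulate_trials(obs, ConditionSpec(("D",)), n_reps=12, seed=1, condition_label="D"),
    simulate_trials(obs, ConditionSpec(("S",)), n_reps=12, seed=2, condition_label="S"),
    simulate_trials(obs, ConditionSpec(("D", "S")), n_reps=12, seed=3, condition_label="DS"),
])
fits = fit_trial_table(trials)
fits["sigma"] = 1 / (fits["beta"] * np.sqrt(2))
print(fits[["condition", "sigma"]], optimal_sigma(0.2, 0.3).sigma_opt)
```

prints (seed-exact):

```
condition   fitted sigma   generative sigma
  D         0.189          0.200
  DS        0.161          0.166
  S         0.293          0.300
```

The fitted bimodal noise (0.161) lands on the ideal-observer prediction
(0.166) and below both single cues — the combination signature.  The
`examples/` directory has one short script per capability: stimulus mappings,
simulate-and-fit, integration markers, group analysis with exclusions,
repeatability, and power.

## Command line

A thin CLI mirrors the pipeline stages:

```
cuecombine simulate --config cfg.yaml --seed 1 --out trials.csv
cuecombine fit --trials trials.csv --out fits.csv
cuecombine markers --fits fits.csv --out metrics.csv
cuecombine analyze --metrics metrics.csv --fits fits.csv --out-dir results/
cuecombine repeatability --data long.csv --n-boot 10000 --n-perm 1000 --seed 1 --out rep.csv
cuecombine power --sigma-best 0.2 --ratio 1.5 --n 30 --sims 1000 --seed 1 --out power.csv
cuecombine run --seed 1 --out-dir artifacts/      # end-to-end, deterministic
```

## Layout

```
src/cuecombine/
  design.py        stimulus geometry, depth grid, condition specs
  observers.py     generative observers and study-scale simulation
  psychofit.py     two-stage Bayesian psychometric fitting (grid posterior)
  metrics.py       sigma/JND, weights, optimal predictions, CI/RI/IS
  stats.py         Wilcoxon, McNemar, JZS Bayes factor conventions
  group.py         exclusion rules and group hypothesis tests
  repeatability.py one-way REML, bootstrap CI, LRT, permutation
  power.py         simulation-based power over design grids
  pipeline.py      config, end-to-end runner, named fixtures
  cli.py           thin click wrapper
```

See `docs/methods.md` for the modelling assumptions, parameter conventions
and known limitations.
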