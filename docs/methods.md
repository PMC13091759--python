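# Methods

## Generative observer model

A simulated observer holds single-estimate sensory noises (normalized depth
units) for binocular disparity (`sigma_D`), size (`sigma_S`), audio
(`sigma_A`), and an uncertainty-added disparity variant (`sigma_Du`, default
`2 * sigma_D`; the display-side dot jitter that motivates this condition has
no recoverable mapping to an internal noise value, so the inflation factor is
a model parameter, exposed in the profile).  On each 2IFC trial the observer
forms one internal depth estimate per interval from the available cues and
reports which interval was further.

Strategies:

* **optimal** — inverse-variance averaging of the two cues; fused noise
  `sqrt(s1^2 s2^2/(s1^2+s2^2))`.
* **best-single** — only the lower-noise cue is consulted.
* **switching(p)** — one cue per trial with probability `p` (default:
  reliability-proportional).  Matches re-weighting phenomenology without a
  precision benefit: the response function is a mixture of two normal CDFs
  whose effective noise exceeds the best single cue.

An observer with `binds_novel_cue=False` treats pairings involving the novel
audio cue as best-single even under the optimal strategy, modelling a causal
inference belief that the novel cue does not share a source with disparity.

Conflicts displace the *reference's* non-disparity cue by `delta` (set per
participant at 1.5 x the JND of the conflicted cue, matching how such offsets
are scheduled from earlier single-cue estimates); incongruent blocks negate
the comparison's non-disparity cue relative to the learned mapping.  Both
manipulations are exact in the closed-form response probability
(`response_probability`), which the trial-level sampler is tested against;
study-scale simulation suites sample binomial counts from those
probabilities, which is distribution-identical to trial-level simulation
after interval-order recoding.

**Lapses.** With probability `lambda` the observer reports "comparison
further" regardless of the stimulus.  This matches the fitted model's
asymmetric asymptotes (lower `lambda`, upper 1) exactly, so generative and
fitted parameters coincide; the field's conventional symmetric guessing rule
is available via `lapse_convention="half"`.  The asymmetric rule is a
modelling convenience, not a claim about attention: on real data the two
conventions differ only in how lapses distribute over the two response
categories.

**Design.** 14 comparison levels at +/-{0.10 ... 1.00} (steps of 0.15), 12
repetitions per level (168 main trials) or a total-trials target distributed
round-robin over levels (the session schedule uses 150/condition); 4% "easy"
trials present the two extreme depths against each other, are flagged, and
are excluded from fits by default.  Interval order is a fair coin; the
recorded response is the raw "second interval further" judgment plus a
`reference_interval` column that the fitting stage uses for recoding.  All
stochastic operations take explicit seeds; study-scale generation uses one
master seed with per-participant substreams.

## Two-stage psychometric fitting

Likelihood: Bernoulli with `psi(x) = lambda + (1-lambda) * Phi(beta (x -
alpha))`.  Priors are uniform: `beta` on (0.02, 200] (log-spaced grid,
trapezoid quadrature, so the prior is uniform in `beta`, not log-beta),
`alpha` on [-1, 1] where free (conflict conditions) else fixed at 0, `lambda`
on [0, 0.2].  Point estimates are posterior means; credible intervals are
2.5/97.5% quantiles of the marginal grid posterior.  A dense grid rather than
MCMC keeps fits deterministic and fast enough to vectorise over hundreds of
observers; halving the grid spacing moves slope estimates by well under 1%
(tested).

Stage 1 estimates a single lapse per participant x session jointly across
conditions (condition-specific slopes marginalised under their priors);
stage 2 fixes that lapse and fits each condition's slope (and PSE where
free).  Fixing the lapse demonstrably lowers the RMSE of the slope versus
per-condition free-lapse fits (tested on 100 replicates).  In study-scale
replicate suites the lapse stage uses the PSE-fixed conditions only;
marginalising the conflict conditions' free PSE inside the lapse stage is
supported in the per-table API but needs tensors too large for
hundreds-of-studies loops.  The lapse information lives almost entirely in
the asymptote trials of the high-count congruent conditions, so the
restriction is immaterial in practice.

The slope posterior at ~170-trial blocks is right-skewed, so the posterior
*mean* of `beta` overstates the slope and understates `sigma` by 5-10%
(measured; the grid MAP, available as `point="mode"`, is median-unbiased for
`sigma` within ~5%).  The skew bias is shared across an observer's conditions
and cancels in the paired contrasts (combination benefit, weight changes)
that every group analysis uses, which is why the mean remains the default
summary.

Degenerate inputs: fewer than 20 usable trials is refused; all-same
responses are flagged `degenerate`; separable (step-function) data drive the
slope to its upper prior bound and are flagged `boundary` (likelihood within
0.5 log-units of the maximum at a grid edge).

## Markers and conventions

* `sigma = 1/(beta sqrt(2))`, `JND = 1/beta`.
* Empirical weight from the signed half-difference of the +delta and -delta
  PSEs, `mu_PSE = (pse_plus - pse_minus)/2`, which cancels any
  conflict-independent bias; `w_emp = 1 - mu_PSE/delta` with `delta`
  recomputed from the participant's fitted single-cue JND (session 2 by
  default), mirroring how the physical conflicts are scheduled.
* Predicted weight `w_D = s_other^2/(s_D^2 + s_other^2)` — the inverse-
  variance form consistent with the PSE-shift convention above (the
  alternative algebraic rendering, `1 - s_D^{-2}/(s_D^{-2}+s_other^{-2})`,
  contradicts it and is not used).
* `CI` is reported in absolute noise units (benefit over the best single
  cue); an optimally-scaled variant is a trivial post-hoc division and was
  deliberately not added to the table.
* Missing conditions yield absent (NaN) indices, never zeros.

## Group analysis

Exclusion fences are two-sided `median +/- 2.5 IQR` per measure (IQR = 0
excludes nothing): disparity-noise violators leave all analyses, size/audio
violators leave their cue pair, fitted lapse >= 0.10 (median across sessions)
leaves everything, and inverse audio mappers (negative response-level
correlation in the audio block, used instead of a fitted-slope sign because
the slope prior is positive) leave the familiar-novel analyses.

Hypothesis tests: two-tailed Wilcoxon signed-rank throughout (zeros dropped;
exact null for n < 50 without ties, as in R's `wilcox.test`, else normal
approximation with continuity correction); McNemar on the discordant
classification cells with continuity-corrected chi-square by default (exact
binomial available); OLS regression of empirical on predicted weights;
the nuisance-cue control uses a one-sided signed-rank (rank-sum optional —
the design is within-observer, so paired is the default) plus a JZS paired-t
Bayes factor with Cauchy scale `sqrt(2)/2`.

## Repeatability

One-way random-intercept Gaussian model fit by REML (1-D profile over the
variance ratio; the profile likelihood is exact, no iterative matrix
algebra), `R = sigma_G^2/(sigma_G^2 + sigma_R^2)`.  On balanced data this
equals the one-way ANOVA ICC, which is kept as an independent oracle.
Uncertainty: parametric bootstrap (percentile CI; refits on data simulated
from the fitted model; failed refits counted and excluded).  Significance:
LRT against the intercept-only model with the 50:50 {0, chi2_1} boundary
mixture, and permutation of reduced-model residuals.  Session enters as
exchangeable replicate (no fixed session effect); a log-transform option
suits sigma-type measures.  Measures are assumed Gaussian on the analysis
scale.

## Power simulations

Each cell (n, sigma_best, noise_ratio) simulates complete experiments:
per-observer lapse uniform on [0, 0.10]; three conditions (best, worst at
ratio x best, combined at the optimal prediction), 14 x 12 trials each;
per-condition single-stage Bayesian fits with alpha, beta and lambda jointly
free (the protocol an a-priori power analysis uses — the shared-lapse
two-stage refinement presupposes the pooled fitting machinery of the final
pipeline and markedly shrinks estimator noise, which would overstate
prospective power; `fit_mode="two-stage"` switches to it); group two-tailed
Wilcoxon of combined vs the per-observer minimum of the two fitted single-cue
sigmas.  A success is p < 0.05 with the median difference favouring
combination; the undirected rejection rate is reported alongside and sits at
the nominal 0.05 under a best-single-cue (null) population.

All observers in a cell share the cell's sigmas by default — the reading
under which "best-cue noise 0.2" is well-posed — with an optional lognormal
population jitter (`heterogeneity_cv`).  The power evaluation grid
(141 beta x 25 alpha x 11 lambda points) was fixed by a convergence study:
group effect sizes change by ~1% against a 281 x 57 x 29 grid, while a
1,000-experiment cell runs in roughly one to four minutes on one CPU.

Known discrepancy: with these conditions the n=60 / ratio-2 cell yields
~72-74% power, a few points above the 65.5% working value this cell is often
quoted at, while the n=30 / ratio-1.5 cell reproduces its ~80% value.  The
two quoted values jointly imply effect sizes of ~0.52 and ~0.31, a ratio no
single fitting protocol we examined produces; the residual gap likely
reflects unreported details of the original simulation code.

## What the synthetic data do and do not show

The generator reproduces the design's structure (condition schedules,
conflict scaling, easy trials, counterbalanced mappings, between- and
within-observer variance in noise parameters) and exactly known response
statistics.  It does not emulate sequential effects, adaptation,
attention drifts within blocks, non-stationary lapsing, or violations of the
cumulative-normal form — so green tests certify that the *pipeline* recovers
truth under its own model class, not that real observers satisfy the model.
Problem sizes in the test suite (e.g. 100-observer recovery runs, 200
replicate studies at n = 40, 200-replicate repeatability recovery with
200-sample bootstraps, 300-1,000 power simulations per cell) were chosen to
make Monte-Carlo error small relative to each assertion's margin.
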