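"""Generative 2IFC observers: noisy cue estimates, combination strategies, lapses.

Each simulated observer holds single-cue sensory noises (normalized depth units)
and a perceptual-decisional strategy.  On every trial the observer forms an
internal estimate of each interval's depth from the available cues and judges
which interval was further.  Strategies:

``"optimal"``
    Reliability-weighted (inverse-variance) averaging of the two cues; the fused
    single-interval noise is sqrt(s1^2 s2^2 / (s1^2 + s2^2)).
``"best-single"``
    Only the lower-noise cue is consulted.
``"switching"``
    One cue is used per trial, chosen with probability ``switch_p`` (default:
    reliability-proportional).  Mimics re-weighting without a precision benefit.

Lapses follow the fitted model's asymptotes: with probability ``lapse`` the
observer reports "comparison further" regardless of the stimulus, so a fitted
psychometric function psi = lambda + (1 - lambda) F recovers the generative
parameters exactly.  The conventional guessing rule (respond at random on a
lapse trial) is available as ``lapse_convention="half"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .design import ConditionSpec, DepthDesign, condition_from_label

__all__ = [
    "ObserverProfile",
    "PopulationSpec",
    "DEFAULT_SESSION_SCHEDULE",
    "response_probability",
    "percept_sample",
    "simulate_trials",
    "simulate_study",
]

_SQRT2 = np.sqrt(2.0)

TRIAL_COLUMNS = [
    "participant", "session", "condition", "mapping_direction", "side",
    "comparison_level", "conflict_sign", "easy", "reference_interval", "response",
]


@dataclass(frozen=True)
class ObserverProfile:
    """Generative ground truth for one simulated participant.

    Noises are single-estimate standard deviations in normalized depth units;
    discrimination (2IFC) noise is sqrt(2) larger because two noisy intervals
    are compared.
    """

    sigma_D: float = 0.2
    sigma_S: float = 0.3
    sigma_A: float = 0.3
    sigma_Du: float | None = None  # default: 2 * sigma_D
    lapse: float = 0.0
    strategy: str = "optimal"
    switch_p: float | None = None
    mapping_direction: int = 1
    binds_novel_cue: bool = True
    lapse_convention: str = "printed"  # "printed" (asymptotes lambda, 1) or "half"

    def __post_init__(self) -> None:
        for name in ("sigma_D", "sigma_S", "sigma_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_Du is not None and self.sigma_Du <= 0:
            raise ValueError("sigma_Du must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")
        if self.strategy not in ("optimal", "best-single", "switching"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.mapping_direction not in (1, -1):
            raise ValueError("mapping_direction must be +1 or -1")
        if self.lapse_convention not in ("printed", "half"):
            raise ValueError("lapse_convention must be 'printed' or 'half'")

    def sigma_for(self, cue: str, noisy: bool = False) -> float:
        if cue == "D":
            if noisy:
                return self.sigma_Du if self.sigma_Du is not None else 2.0 * self.sigma_D
            return self.sigma_D
        if cue == "S":
            return self.sigma_S
        if cue == "A":
            return self.sigma_A
        raise KeyError(cue)

    def condition_sigmas(self, spec: ConditionSpec) -> dict[str, float]:
        return {c: self.sigma_for(c, spec.disparity_noisy and c == "D") for c in spec.cues}


def _strategy_for(obs: ObserverProfile, spec: ConditionSpec) -> str:
    """Effective strategy: an observer that does not bind the novel cue never
    averages a pairing that includes audio."""
    if spec.is_bimodal and "A" in spec.cues and not obs.binds_novel_cue \
            and obs.strategy == "optimal":
        return "best-single"
    return obs.strategy


def _cue_values(spec: ConditionSpec, comparison_level, reference_level=0.0):
    """True cue values (normalized) per cue for (reference, comparison) intervals.

    The conflict offset displaces the *reference's* non-disparity cue; an
    incongruent condition negates the comparison's non-disparity cue relative to
    the learned mapping.
    """
    x = np.asarray(comparison_level, dtype=float)
    ref = {c: np.full_like(x, float(reference_level)) for c in spec.cues}
    comp = {c: x.copy() for c in spec.cues}
    other = spec.other_cue
    if spec.conflict_delta != 0.0 and other is not None:
        ref[other] = ref[other] + spec.conflict_delta
    if spec.incongruent and other is not None:
        comp[other] = -comp[other]
    return ref, comp


def _apply_lapse(p_further, lapse: float, convention: str):
    if convention == "printed":
        return lapse + (1.0 - lapse) * p_further
    return lapse / 2.0 + (1.0 - lapse) * p_further


def response_probability(comparison_level, spec: ConditionSpec, obs: ObserverProfile,
                         reference_level: float = 0.0) -> np.ndarray:
    """Exact P("comparison further") at each comparison level.

    Closed-form counterpart of :func:`percept_sample`; used as the binomial
    sampling kernel in study-scale simulation and as the oracle against which the
    trial-level simulator is tested.
    """
    sigmas = obs.condition_sigmas(spec)
    ref, comp = _cue_values(spec, comparison_level, reference_level)
    strategy = _strategy_for(obs, spec)
    cues = list(spec.cues)

    if len(cues) == 1 or strategy == "best-single":
        cue = cues[0] if len(cues) == 1 else min(cues, key=lambda c: sigmas[c])
        s = sigmas[cue]
        p = ndtr((comp[cue] - ref[cue]) / (s * _SQRT2))
    elif strategy == "optimal":
        c1, c2 = cues
        v1, v2 = sigmas[c1] ** 2, sigmas[c2] ** 2
        w1 = v2 / (v1 + v2)
        mu = w1 * (comp[c1] - ref[c1]) + (1 - w1) * (comp[c2] - ref[c2])
        s_f = np.sqrt(v1 * v2 / (v1 + v2))
        p = ndtr(mu / (s_f * _SQRT2))
    else:  # switching
        c1, c2 = cues
        p_first = obs.switch_p
        if p_first is None:  # reliability-proportional
            v1, v2 = sigmas[c1] ** 2, sigmas[c2] ** 2
            p_first = v2 / (v1 + v2)
        p = (p_first * ndtr((comp[c1] - ref[c1]) / (sigmas[c1] * _SQRT2))
             + (1 - p_first) * ndtr((comp[c2] - ref[c2]) / (sigmas[c2] * _SQRT2)))
    return _apply_lapse(p, obs.lapse, obs.lapse_convention)


def percept_sample(comparison_level, spec: ConditionSpec, obs: ObserverProfile,
                   rng: np.random.Generator, reference_level: float = 0.0):
    """Sample the observer's internal (reference, comparison) depth estimates.

    Returns a pair of arrays broadcast to the shape of ``comparison_level``.
    """
    if "A" in spec.cues and obs.mapping_direction not in (1, -1):
        raise ValueError("audio cue requires a mapping direction")
    sigmas = obs.condition_sigmas(spec)
    ref, comp = _cue_values(spec, comparison_level, reference_level)
    strategy = _strategy_for(obs, spec)
    cues = list(spec.cues)
    shape = np.asarray(comparison_level, dtype=float).shape

    def noisy(values, cue):
        return values + rng.normal(0.0, sigmas[cue], size=np.shape(values))

    if len(cues) == 1 or strategy == "best-single":
        cue = cues[0] if len(cues) == 1 else min(cues, key=lambda c: sigmas[c])
        return noisy(ref[cue], cue), noisy(comp[cue], cue)
    if strategy == "optimal":
        c1, c2 = cues
        v1, v2 = sigmas[c1] ** 2, sigmas[c2] ** 2
        w1 = v2 / (v1 + v2)
        r = w1 * noisy(ref[c1], c1) + (1 - w1) * noisy(ref[c2], c2)
        c = w1 * noisy(comp[c1], c1) + (1 - w1) * noisy(comp[c2], c2)
        return r, c
    # switching: one cue per trial, used on both intervals
    c1, c2 = cues
    p_first = obs.switch_p
    if p_first is None:
        v1, v2 = sigmas[c1] ** 2, sigmas[c2] ** 2
        p_first = v2 / (v1 + v2)
    use_first = rng.random(size=shape) < p_first
    r = np.where(use_first, noisy(ref[c1], c1), noisy(ref[c2], c2))
    c = np.where(use_first, noisy(comp[c1], c1), noisy(comp[c2], c2))
    return r, c


def _reps_per_level(n_levels: int, n_reps: int | None, n_trials: int | None) -> np.ndarray:
    if n_trials is None:
        if n_reps is None or n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        return np.full(n_levels, int(n_reps), dtype=int)
    base, extra = divmod(int(n_trials), n_levels)
    reps = np.full(n_levels, base, dtype=int)
    reps[:extra] += 1  # round-robin remainder, deterministic
    return reps


def simulate_trials(obs: ObserverProfile, spec: ConditionSpec,
                    design: DepthDesign = DepthDesign(), n_reps: int | None = 12,
                    seed=None, *, n_trials: int | None = None,
                    participant="p1", session=2,
                    condition_label: str | None = None) -> pd.DataFrame:
    """Simulate one condition block using the method of constant stimuli.

    ``n_reps`` repetitions per comparison level (or ``n_trials`` total,
    distributed as evenly as possible over the levels), plus easy trials at the
    design's stated rate in which the two extreme depths are shown against each
    other.  Interval order is randomized with a fair coin and the recorded
    ``response`` is the raw judgment (1 = "second interval further"); the
    ``reference_interval`` column allows recoding to comparison-vs-reference.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    levels = design.levels
    reps = _reps_per_level(len(levels), n_reps, n_trials)
    x_main = np.repeat(levels, reps)

    n_easy = design.n_easy(len(x_main))
    hi, lo = levels.max(), levels.min()
    easy_sign = rng.random(n_easy) < 0.5
    x_easy = np.where(easy_sign, hi, lo)
    ref_easy = np.where(easy_sign, lo, hi)

    x = np.concatenate([x_main, x_easy])
    ref_level = np.concatenate([np.zeros_like(x_main), ref_easy])
    easy = np.concatenate([np.zeros(len(x_main), bool), np.ones(n_easy, bool)])

    order = rng.permutation(len(x))
    x, ref_level, easy = x[order], ref_level[order], easy[order]

    # easy trials carry no conflict/incongruence manipulation
    spec_easy = replace(spec, conflict_delta=0.0, incongruent=False) \
        if (spec.conflict_delta != 0.0 or spec.incongruent) else spec

    comp_further = np.empty(len(x), bool)
    for s, mask in ((spec, ~easy), (spec_easy, easy)):
        if mask.any():
            r_est, c_est = percept_sample(x[mask], s, obs, rng,
                                          reference_level=0.0)
            # easy trials put the reference at the opposite extreme
            r_est = r_est + ref_level[mask]
            comp_further[mask] = c_est > r_est

    lapses = rng.random(len(x)) < obs.lapse
    if obs.lapse_convention == "printed":
        comp_further[lapses] = True
    else:
        comp_further[lapses] = rng.random(lapses.sum()) < 0.5

    reference_interval = rng.integers(1, 3, size=len(x))
    second_further = np.where(reference_interval == 1, comp_further, ~comp_further)

    label = condition_label if condition_label is not None else spec.label
    return pd.DataFrame({
        "participant": participant,
        "session": session,
        "condition": label,
        "mapping_direction": obs.mapping_direction,
        "side": design.side,
        "comparison_level": x,
        "conflict_sign": int(np.sign(spec.conflict_delta)),
        "easy": easy,
        "reference_interval": reference_interval,
        "response": second_further.astype(int),
    })


# ---------------------------------------------------------------------------
# study-scale generation


#: condition blocks per session, following the study's schedule: sessions 2 and 4
#: test the plain cues (session 2 adds the conflict blocks, session 4 the
#: incongruent blocks); session 3 tests the noisy-disparity variants.
DEFAULT_SESSION_SCHEDULE = {
    2: ["D", "S", "A", "DS", "DA", "DS+", "DS-", "DA+", "DA-"],
    3: ["Du", "S", "A", "DuS", "DuA", "DuS+", "DuS-", "DuA+", "DuA-"],
    4: ["D", "S", "A", "DS", "DA", "DSi", "DAi"],
}


@dataclass(frozen=True)
class PopulationSpec:
    """Distributions over observer parameters for a simulated cohort.

    Per-parameter values are drawn as participant mean + session perturbation,
    both Gaussian (``between_sd`` = sqrt(sigma_G^2), ``within_sd`` =
    sqrt(sigma_R^2)), truncated at ``sigma_floor`` — the variance structure the
    repeatability module estimates.  Mapping direction is counterbalanced.
    """

    n_participants: int = 20
    mean_sigma_D: float = 0.2
    mean_sigma_S: float = 0.3
    mean_sigma_A: float = 0.3
    between_sd: float = 0.05
    within_sd: float = 0.02
    sigma_Du_factor: float = 2.0
    lapse_range: tuple = (0.0, 0.06)
    strategy: str = "optimal"
    switch_p: float | None = None
    binds_novel_cue: bool = True
    sigma_floor: float = 0.02
    conflict_jnd_multiple: float = 1.5

    def draw_observer(self, rng: np.random.Generator, mapping_direction: int):
        """Draw a participant: per-session profiles sharing one participant mean."""
        means = {
            "sigma_D": rng.normal(self.mean_sigma_D, self.between_sd),
            "sigma_S": rng.normal(self.mean_sigma_S, self.between_sd),
            "sigma_A": rng.normal(self.mean_sigma_A, self.between_sd),
        }
        lapse = rng.uniform(*self.lapse_range)

        def session_profile():
            vals = {k: max(v + rng.normal(0.0, self.within_sd), self.sigma_floor)
                    for k, v in means.items()}
            return ObserverProfile(
                sigma_D=vals["sigma_D"], sigma_S=vals["sigma_S"],
                sigma_A=vals["sigma_A"],
                sigma_Du=self.sigma_Du_factor * vals["sigma_D"],
                lapse=lapse, strategy=self.strategy, switch_p=self.switch_p,
                mapping_direction=mapping_direction,
                binds_novel_cue=self.binds_novel_cue,
            )

        return session_profile


def simulate_study(population: PopulationSpec,
                   sessions: dict | None = None,
                   design: DepthDesign = DepthDesign(),
                   n_trials_per_condition: int = 150,
                   seed=None) -> pd.DataFrame:
    """Simulate a multi-participant, multi-session study.

    Each participant gets an independent RNG substream; per-session observer
    profiles share the participant's mean noise parameters plus a session
    perturbation (see :class:`PopulationSpec`).  Conflict magnitudes are set per
    participant at ``conflict_jnd_multiple`` x the true JND of the conflicted
    (non-disparity) cue, as the study scheduled them from session-2 estimates.
    """
    if sessions is None:
        sessions = DEFAULT_SESSION_SCHEDULE
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(population.n_participants)]
    frames = []
    for i, rng in enumerate(streams):
        direction = 1 if i % 2 == 0 else -1
        session_profile = population.draw_observer(rng, direction)
        pid = f"p{i + 1:03d}"
        for sess, labels in sessions.items():
            obs = session_profile()
            for label in labels:
                delta = 0.0
                if label.endswith(("+", "-")):
                    other = "A" if "A" in label else "S"
                    jnd = obs.sigma_for(other) * _SQRT2
                    delta = population.conflict_jnd_multiple * jnd
                spec = condition_from_label(label, conflict_delta=delta)
                frames.append(simulate_trials(
                    obs, spec, design, n_reps=None,
                    n_trials=n_trials_per_condition, seed=rng,
                    participant=pid, session=sess, condition_label=label))
    return pd.concat(frames, ignore_index=True)
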