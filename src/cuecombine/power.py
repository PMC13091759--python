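"""Simulation-based power for detecting a group-level cue-combination benefit.

Each simulated experiment draws ``n_participants`` observers with a best-cue
single-estimate noise ``sigma_best``, a worst cue at ``noise_ratio`` x that,
and a combined condition at the maximum-likelihood optimal prediction
sqrt(s_b^2 s_w^2 / (s_b^2 + s_w^2)); per-observer lapse rates are uniform on
[0, max_lapse].  Every observer contributes 2IFC data (14 comparison levels x
12 repetitions by default) for the three conditions; each condition is fitted
with the classic single-stage Bayesian criterion fit (alpha, beta and lapse
jointly free under uniform priors — the procedure an a-priori power analysis
uses, before any shared-lapse refinement is available; ``fit_mode="two-stage"``
switches to the shared-lapse pipeline).  The experiment then runs the group
two-tailed Wilcoxon signed-rank test of the combined sigma against the best
fitted single-cue sigma (the per-participant minimum of the two single-cue
fits, as in the combination hypothesis test).  Power is the fraction of
experiments with p < alpha and the median difference in the combination
direction.

By default every observer in a cell shares the cell's sigmas (the reading
under which "average best sensory cue noise of 0.2" is well-posed); set
``heterogeneity_cv`` to draw per-observer sigmas lognormally around the cell
values instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .design import COMPARISON_LEVELS
from .psychofit import (GridSpec, fit_beta_grid, fit_lapse_grid,
                        fit_single_stage_grid)
from .stats import wilcoxon_signed_rank

__all__ = ["PowerCell", "simulate_power_cell", "power_grid"]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class PowerCell:
    n_participants: int
    sigma_best: float
    noise_ratio: float
    max_lapse: float
    n_sims: int
    power: float            # p < alpha AND median difference favours combination
    rejection_rate: float   # p < alpha regardless of direction
    mc_se: float
    alpha: float = 0.05
    n_discarded: int = 0

    def as_dict(self) -> dict:
        return {
            "n_participants": self.n_participants, "sigma_best": self.sigma_best,
            "noise_ratio": self.noise_ratio, "max_lapse": self.max_lapse,
            "n_sims": self.n_sims, "power": self.power,
            "rejection_rate": self.rejection_rate, "mc_se": self.mc_se,
            "alpha": self.alpha, "n_discarded": self.n_discarded,
        }


def _cell_sigmas(rng, n_participants, sigma_best, noise_ratio, strategy,
                 heterogeneity_cv):
    """(P, 3) single-estimate sigmas for (best, worst, combined)."""
    if heterogeneity_cv:
        s2 = np.log1p(heterogeneity_cv ** 2)
        s_b = sigma_best * np.exp(rng.normal(-s2 / 2, np.sqrt(s2), n_participants))
    else:
        s_b = np.full(n_participants, sigma_best)
    s_w = noise_ratio * s_b
    if strategy == "optimal":
        s_c = np.sqrt(s_b ** 2 * s_w ** 2 / (s_b ** 2 + s_w ** 2))
    elif strategy == "best-single":
        s_c = s_b.copy()
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return np.stack([s_b, s_w, s_c], axis=1)


#: default evaluation grid for power simulations: coarser than the analysis
#: default so that a 1,000-experiment cell stays desk-scale, but still several
#: grid points per posterior standard deviation at study-like slopes.
POWER_GRID = GridSpec.make(n_beta=141, n_alpha=25, n_lam=11)


def _fit_experiment_sigmas(k, n_reps, levels, grid, fit_mode) -> np.ndarray:
    """Fitted sigma (P, C) from binomial counts (P, C, L)."""
    n = np.full(k.shape, float(n_reps))
    if fit_mode == "per-condition":
        beta_hat = fit_single_stage_grid(k, n, levels, grid)["beta"]
    elif fit_mode == "two-stage":
        lam_hat = fit_lapse_grid(k, n, levels, grid)
        beta_hat = fit_beta_grid(k, n, levels, lam_hat, grid)["beta"]
    else:
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    return 1.0 / (beta_hat * _SQRT2)


def simulate_power_cell(n_participants: int, sigma_best: float,
                        noise_ratio: float, *, max_lapse: float = 0.10,
                        n_sims: int = 1000, alpha: float = 0.05,
                        levels=COMPARISON_LEVELS, n_reps: int = 12,
                        seed=None, grid: GridSpec | None = None,
                        strategy: str = "optimal",
                        fit_mode: str = "per-condition",
                        heterogeneity_cv: float | None = None) -> PowerCell:
    """Estimate power for one (n, sigma_best, noise_ratio) design cell.

    Returns a :class:`PowerCell`; ``power`` is direction-gated, while
    ``rejection_rate`` counts two-sided rejections regardless of direction
    (the type-I calibration quantity under a null ``strategy="best-single"``).
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid = grid or POWER_GRID
    levels = np.asarray(levels, dtype=float)

    successes = rejections = discarded = 0
    for _ in range(n_sims):
        sig = _cell_sigmas(rng, n_participants, sigma_best, noise_ratio,
                           strategy, heterogeneity_cv)
        lam = rng.uniform(0.0, max_lapse, n_participants)
        p = lam[:, None, None] + (1.0 - lam[:, None, None]) * ndtr(
            levels / (sig[:, :, None] * _SQRT2))
        k = rng.binomial(n_reps, p).astype(float)
        try:
            sig_hat = _fit_experiment_sigmas(k, n_reps, levels, grid, fit_mode)
        except Exception:
            discarded += 1
            continue
        best_hat = np.minimum(sig_hat[:, 0], sig_hat[:, 1])
        res = wilcoxon_signed_rank(sig_hat[:, 2], best_hat)
        if res.p_value < alpha:
            rejections += 1
            if np.median(sig_hat[:, 2] - best_hat) < 0:
                successes += 1
    n_eff = n_sims - discarded
    power = successes / n_eff if n_eff else float("nan")
    mc_se = float(np.sqrt(power * (1 - power) / n_eff)) if n_eff else float("nan")
    return PowerCell(n_participants=n_participants, sigma_best=sigma_best,
                     noise_ratio=noise_ratio, max_lapse=max_lapse,
                     n_sims=n_eff, power=power,
                     rejection_rate=rejections / n_eff if n_eff else float("nan"),
                     mc_se=mc_se, alpha=alpha, n_discarded=discarded)


def power_grid(sigma_best_values, noise_ratios, ns, *, max_lapse: float = 0.10,
               n_sims: int = 1000, alpha: float = 0.05,
               levels=COMPARISON_LEVELS, n_reps: int = 12, seed=None,
               grid: GridSpec | None = None, fit_mode: str = "per-condition",
               heterogeneity_cv: float | None = None) -> pd.DataFrame:
    """Power over the Cartesian grid sigma_best x noise_ratio x n.

    Each cell runs on an independent RNG substream of ``seed``; the result is a
    DataFrame with one row per cell (all :class:`PowerCell` fields).
    """
    cells = list(itertools.product(sigma_best_values, noise_ratios, ns))
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    streams = ss.spawn(len(cells))
    rows = []
    for (s_b, ratio, n), child in zip(cells, streams):
        cell = simulate_power_cell(
            int(n), float(s_b), float(ratio), max_lapse=max_lapse,
            n_sims=n_sims, alpha=alpha, levels=levels, n_reps=n_reps,
            seed=np.random.default_rng(child), grid=grid, fit_mode=fit_mode,
            heterogeneity_cv=heterogeneity_cv)
        rows.append(cell.as_dict())
    return pd.DataFrame(rows)
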