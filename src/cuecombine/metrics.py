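"""Derived integration quantities: sensory noise, JND, cue weights, markers.

All quantities live in normalized depth units.  A 2IFC discrimination compares
two noisy interval estimates, so the single-estimate sensory noise is the
discrimination SD divided by sqrt(2):

    sigma = 1 / (beta * sqrt(2)),      JND = sigma * sqrt(2) = 1 / beta.

Cue weights follow the reliability-weighted (inverse-variance) averaging model:
the predicted disparity weight is w_D = sigma_other^2 / (sigma_D^2 +
sigma_other^2), and the empirical weight is read out of the conflict-induced PSE
shift, w_emp = 1 - mu_PSE / delta with mu_PSE the signed half-difference of the
PSEs under +delta and -delta conflicts.  Marker indices per participant and cue
pair:

    CI = min(single-cue sigmas) - bimodal sigma        (combination)
    RI = w_emp(normal) - w_emp(noisy disparity)        (re-weighting)
    IS = incongruent sigma - congruent sigma           (incongruence sensitivity)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NoiseEstimate",
    "WeightEstimate",
    "OptimalPrediction",
    "MarkerIndices",
    "sigma_from_beta",
    "conflict_magnitude",
    "empirical_weight",
    "predicted_weight",
    "optimal_sigma",
    "marker_indices",
    "metrics_from_fits",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class NoiseEstimate:
    sigma: float
    jnd: float
    source: str = ""


@dataclass(frozen=True)
class WeightEstimate:
    w_emp: float
    w_pred: float | None
    delta: float
    mu_pse: float

    @property
    def flagged(self) -> bool:
        """Empirical weights far outside [0, 1] signal unstable conflict fits."""
        return not -0.5 <= self.w_emp <= 1.5


@dataclass(frozen=True)
class OptimalPrediction:
    sigma_opt: float
    components: tuple


@dataclass(frozen=True)
class MarkerIndices:
    cue_pair: str
    CI: float | None = None
    RI: float | None = None
    IS: float | None = None


def sigma_from_beta(beta, source: str = "") -> NoiseEstimate:
    """Single-estimate sensory noise and JND from a psychometric slope."""
    beta = float(beta)
    if beta <= 0:
        raise ValueError("beta must be positive")
    return NoiseEstimate(sigma=1.0 / (beta * _SQRT2), jnd=1.0 / beta, source=source)


def conflict_magnitude(jnd, multiple: float = 1.5) -> float:
    """Conflict offset delta = ``multiple`` x JND of the conflicted cue."""
    jnd = float(jnd)
    if jnd <= 0:
        raise ValueError("JND must be positive")
    return multiple * jnd


def empirical_weight(pse_plus, pse_minus, delta,
                     w_pred: float | None = None) -> WeightEstimate:
    """Disparity weight from conflict-induced PSE shifts.

    mu_PSE = (pse_plus - pse_minus) / 2 averages the +delta and -delta shifts
    with opposite signs, cancelling any conflict-independent bias;
    w_emp = 1 - mu_PSE / delta equals 1 when the PSEs do not move (disparity
    fully followed) and 0 when they move by the full conflict.
    """
    delta = float(delta)
    if delta <= 0:
        raise ValueError("delta must be positive")
    mu = (float(pse_plus) - float(pse_minus)) / 2.0
    return WeightEstimate(w_emp=1.0 - mu / delta, w_pred=w_pred, delta=delta, mu_pse=mu)


def predicted_weight(sigma_d_like, sigma_other) -> float:
    """Reliability-predicted disparity weight w_D = s_o^2 / (s_D^2 + s_o^2)."""
    sd, so = float(sigma_d_like), float(sigma_other)
    if sd <= 0 or so <= 0:
        raise ValueError("sigmas must be positive")
    return so ** 2 / (sd ** 2 + so ** 2)


def optimal_sigma(sigma1, sigma2) -> OptimalPrediction:
    """Maximum-likelihood (inverse-variance) prediction for the bimodal noise."""
    s1, s2 = float(sigma1), float(sigma2)
    if s1 <= 0 or s2 <= 0:
        raise ValueError("sigmas must be positive")
    v1, v2 = s1 ** 2, s2 ** 2
    return OptimalPrediction(sigma_opt=math.sqrt(v1 * v2 / (v1 + v2)),
                             components=(s1, s2))


def marker_indices(sigmas: dict, weights: dict | None = None,
                   cue_pair: str = "DS") -> MarkerIndices:
    """Combination / re-weighting / incongruence indices for one participant.

    Parameters
    ----------
    sigmas : dict
        Condition label -> fitted sigma, e.g. {"D": .., "S": .., "DS": ..,
        "DSi": ..}.  Missing conditions leave the corresponding index ``None``
        (absent, never zero).
    weights : dict, optional
        {"normal": w_emp, "noisy": w_emp} empirical disparity weights.
    cue_pair : {"DS", "DA"}
    """
    if cue_pair not in ("DS", "DA"):
        raise ValueError("cue_pair must be 'DS' or 'DA'")
    other = cue_pair[1]
    ci = ri = is_ = None
    if all(c in sigmas for c in ("D", other, cue_pair)):
        ci = min(sigmas["D"], sigmas[other]) - sigmas[cue_pair]
    if weights is not None and "normal" in weights and "noisy" in weights:
        ri = weights["normal"] - weights["noisy"]
    if cue_pair in sigmas and (cue_pair + "i") in sigmas:
        is_ = sigmas[cue_pair + "i"] - sigmas[cue_pair]
    return MarkerIndices(cue_pair=cue_pair, CI=ci, RI=ri, IS=is_)


# ---------------------------------------------------------------------------
# table-level


def _sigma_of(row) -> float:
    return 1.0 / (row * _SQRT2)


def metrics_from_fits(fits: pd.DataFrame, conflict_multiple: float = 1.5,
                      jnd_session: int = 2) -> pd.DataFrame:
    """Per-participant metrics table from a fits table.

    For every participant and cue pair (DS, DA) this computes the single-cue and
    bimodal sigmas (averaged over sessions where a condition repeats), the
    conflict magnitude delta (``conflict_multiple`` x the participant's
    single-cue JND of the conflicted cue from ``jnd_session``), empirical and
    predicted weights for the normal and noisy disparity variants, the optimal
    bimodal prediction and the CI/RI/IS marker indices.  Missing conditions
    yield NaN, never zero.
    """
    df = fits.copy()
    df["sigma"] = _sigma_of(df["beta"])
    rows = []
    for pid, dp in df.groupby("participant", observed=True):
        def sig(label, session=None):
            d = dp[dp["condition"] == label]
            if session is not None:
                d = d[d["session"] == session]
            return float(d["sigma"].mean()) if len(d) else np.nan

        def pse(label):
            d = dp[dp["condition"] == label]
            return float(d["alpha"].mean()) if len(d) else np.nan

        rec = {"participant": pid, "lambda": float(dp["lambda"].mean())}
        for pair in ("DS", "DA"):
            other = pair[1]
            s_d, s_du = sig("D"), sig("Du")
            s_o = sig(other)
            s_bi, s_bi_noisy = sig(pair), sig("Du" + other)
            s_inc = sig(pair + "i")
            s_o_ref = sig(other, session=jnd_session)
            if np.isnan(s_o_ref):
                s_o_ref = s_o
            delta = conflict_multiple * s_o_ref * _SQRT2 if s_o_ref > 0 else np.nan

            def w_emp_of(prefix):
                p_plus, p_minus = pse(prefix + "+"), pse(prefix + "-")
                if np.isnan(p_plus) or np.isnan(p_minus) or not np.isfinite(delta):
                    return np.nan
                return empirical_weight(p_plus, p_minus, delta).w_emp

            w_emp_n = w_emp_of(pair)
            w_emp_u = w_emp_of("Du" + other)
            w_pred_n = (predicted_weight(s_d, s_o)
                        if np.isfinite(s_d) and np.isfinite(s_o) else np.nan)
            w_pred_u = (predicted_weight(s_du, s_o)
                        if np.isfinite(s_du) and np.isfinite(s_o) else np.nan)
            s_opt = (optimal_sigma(s_d, s_o).sigma_opt
                     if np.isfinite(s_d) and np.isfinite(s_o) else np.nan)
            ci = (min(s_d, s_o) - s_bi
                  if np.isfinite(s_d) and np.isfinite(s_o) and np.isfinite(s_bi)
                  else np.nan)
            ri = (w_emp_n - w_emp_u
                  if np.isfinite(w_emp_n) and np.isfinite(w_emp_u) else np.nan)
            is_ = (s_inc - s_bi
                   if np.isfinite(s_inc) and np.isfinite(s_bi) else np.nan)
            sfx = f"_{pair}"
            rec.update({
                f"sigma_D{sfx}": s_d, f"sigma_Du{sfx}": s_du,
                f"sigma_{other}{sfx}": s_o, f"sigma_bi{sfx}": s_bi,
                f"sigma_bi_noisy{sfx}": s_bi_noisy, f"sigma_inc{sfx}": s_inc,
                f"jnd_{other}{sfx}": (s_o * _SQRT2 if np.isfinite(s_o) else np.nan),
                f"delta{sfx}": delta,
                f"w_emp_normal{sfx}": w_emp_n, f"w_emp_noisy{sfx}": w_emp_u,
                f"w_pred_normal{sfx}": w_pred_n, f"w_pred_noisy{sfx}": w_pred_u,
                f"sigma_opt{sfx}": s_opt,
                f"CI{sfx}": ci, f"RI{sfx}": ri, f"IS{sfx}": is_,
            })
        rows.append(rec)
    return pd.DataFrame(rows)
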