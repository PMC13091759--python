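"""Study-level inference: exclusions, marker hypothesis tests, classification.

The group analyses ask, across participants:

* combination — is the bimodal sensory noise below the best single cue, and
  does it differ from the maximum-likelihood optimal prediction?
* re-weighting — does the empirical disparity weight drop when disparity is
  made unreliable, and does the drop track the reliability-predicted drop?
* incongruence — does reversing the learned cue mapping raise sensory noise?
* cue-pair differences — are the marker indices larger for the familiar pair,
  and do different numbers of participants express each marker per pair
  (McNemar on the discordant classification cells)?

Participants are excluded per measure using a median +/- 2.5 IQR fence,
plus global rules for unusable disparity noise and high lapse rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .psychofit import recode_responses
from .stats import (TestResult, jzs_bayes_factor, mcnemar_test, rank_sum,
                    wilcoxon_signed_rank)

__all__ = [
    "MarkerTestResult",
    "ExclusionReport",
    "iqr_fence_outliers",
    "detect_inverse_mapping",
    "apply_exclusions",
    "test_combination",
    "test_reweighting",
    "test_incongruence",
    "compare_pairs",
    "nuisance_control",
    "analyze_metrics",
    "render_report",
]

LAPSE_EXCLUSION = 0.10
IQR_MULTIPLE = 2.5
MIN_PAIRED = 6


@dataclass(frozen=True)
class MarkerTestResult:
    hypothesis: str
    statistic: float
    p_value: float
    n: int
    direction: str = ""
    method: str = ""


@dataclass(frozen=True)
class ExclusionReport:
    """Per-participant exclusion rules with their scope."""

    entries: pd.DataFrame  # participant, rule, measure, scope

    def excluded(self, scope: str) -> set:
        e = self.entries
        mask = (e["scope"] == "all") | (e["scope"] == scope)
        return set(e.loc[mask, "participant"])

    @property
    def empty(self) -> bool:
        return self.entries.empty


def iqr_fence_outliers(values: pd.Series, multiple: float = IQR_MULTIPLE) -> pd.Series:
    """Two-sided fence: |x - median| > multiple * IQR.  IQR = 0 excludes nothing."""
    v = values.dropna()
    if v.empty:
        return pd.Series(False, index=values.index)
    med = v.median()
    iqr = v.quantile(0.75) - v.quantile(0.25)
    if iqr == 0:
        return pd.Series(False, index=values.index)
    return (values - med).abs() > multiple * iqr


def detect_inverse_mapping(trials: pd.DataFrame, condition: str = "A") -> list:
    """Participants whose audio responses run against the trained mapping.

    Uses the sign of the correlation between comparison level and the recoded
    "comparison further" response in the audio-only condition (the fitted slope
    is constrained positive, so it cannot signal an inverted mapping).
    """
    out = []
    df = trials[trials["condition"] == condition]
    for pid, dp in df.groupby("participant", observed=True):
        x = dp["comparison_level"].to_numpy(float)
        y = recode_responses(dp).astype(float)
        if x.size < 10 or np.all(y == y[0]):
            continue
        r = np.corrcoef(x, y)[0, 1]
        if r < 0:
            out.append(pid)
    return out


def apply_exclusions(metrics: pd.DataFrame, fits: pd.DataFrame | None = None,
                     inverse_mapping_participants=(),
                     iqr_multiple: float = IQR_MULTIPLE):
    """Apply the study's exclusion rules to a per-participant metrics table.

    Rules (scope in parentheses):

    * fitted lapse >= 0.10 across sessions (all analyses),
    * disparity single-cue noise beyond the median +/- ``iqr_multiple`` x IQR
      fence (all analyses),
    * size / audio noise or empirical weight beyond the fence (that cue pair),
    * inverse audio mapping (familiar-novel pair).

    Returns ``(metrics_with_flags, ExclusionReport)``; the returned table gains
    boolean ``include_DS`` / ``include_DA`` columns.
    """
    if len(metrics) < 4:
        raise ValueError("group too small for fence-based exclusion (need >= 4)")
    m = metrics.set_index("participant", drop=False)
    entries = []

    if fits is not None:
        lam = fits.groupby("participant", observed=True)["lambda"].median()
        for pid in lam.index[lam >= LAPSE_EXCLUSION]:
            entries.append((pid, "lapse>=0.10", "lambda", "all"))

    def fence(col, rule, scope):
        if col not in m.columns:
            return
        out = iqr_fence_outliers(m[col], iqr_multiple)
        for pid in m.index[out.fillna(False)]:
            entries.append((pid, rule, col, scope))

    fence("sigma_D_DS", "noise-fence", "all")        # disparity feeds every pairing
    fence("sigma_S_DS", "noise-fence", "DS")
    fence("sigma_A_DA", "noise-fence", "DA")
    fence("w_emp_normal_DS", "weight-fence", "DS")
    fence("w_emp_normal_DA", "weight-fence", "DA")

    for pid in inverse_mapping_participants:
        entries.append((pid, "inverse-mapping", "audio-slope", "DA"))

    report = ExclusionReport(entries=pd.DataFrame(
        entries, columns=["participant", "rule", "measure", "scope"]))
    flagged = metrics.copy()
    for pair in ("DS", "DA"):
        excl = report.excluded(pair)
        flagged[f"include_{pair}"] = ~flagged["participant"].isin(excl)
    if not (flagged["include_DS"] | flagged["include_DA"]).any():
        raise ValueError("no participants left after exclusion")
    return flagged, report


def _included(metrics: pd.DataFrame, cue_pair: str) -> pd.DataFrame:
    col = f"include_{cue_pair}"
    return metrics[metrics[col]] if col in metrics.columns else metrics


def _paired(metrics, cue_pair, col_a, col_b):
    d = _included(metrics, cue_pair)[[col_a, col_b]].dropna()
    return d[col_a].to_numpy(float), d[col_b].to_numpy(float)


def test_combination(metrics: pd.DataFrame, cue_pair: str = "DS"):
    """H1: bimodal sigma vs best single cue, and vs the optimal prediction."""
    sfx = f"_{cue_pair}"
    other = cue_pair[1]
    d = _included(metrics, cue_pair)[
        [f"sigma_D{sfx}", f"sigma_{other}{sfx}", f"sigma_bi{sfx}", f"sigma_opt{sfx}"]
    ].dropna()
    if len(d) < MIN_PAIRED:
        raise ValueError(f"need >= {MIN_PAIRED} paired observations, got {len(d)}")
    best = np.minimum(d[f"sigma_D{sfx}"], d[f"sigma_{other}{sfx}"]).to_numpy()
    bi = d[f"sigma_bi{sfx}"].to_numpy()
    opt = d[f"sigma_opt{sfx}"].to_numpy()

    r1 = wilcoxon_signed_rank(bi, best)
    r2 = wilcoxon_signed_rank(bi, opt)
    dir1 = "bimodal lower" if np.median(bi - best) < 0 else "bimodal higher"
    dir2 = "above optimal" if np.median(bi - opt) > 0 else "below optimal"
    return (MarkerTestResult(f"combination-vs-best[{cue_pair}]", r1.statistic,
                             r1.p_value, r1.n, dir1, r1.method),
            MarkerTestResult(f"combination-vs-optimal[{cue_pair}]", r2.statistic,
                             r2.p_value, r2.n, dir2, r2.method))


def test_reweighting(metrics: pd.DataFrame, cue_pair: str = "DS"):
    """H2: weight drop under noisy disparity; drop vs optimal drop; regression."""
    sfx = f"_{cue_pair}"
    w_n, w_u = _paired(metrics, cue_pair, f"w_emp_normal{sfx}", f"w_emp_noisy{sfx}")
    if w_n.size < MIN_PAIRED:
        raise ValueError(f"need >= {MIN_PAIRED} paired weights, got {w_n.size}")
    r_drop = wilcoxon_signed_rank(w_n, w_u)
    drop_dir = "weight drops" if np.median(w_n - w_u) > 0 else "weight rises"

    d = _included(metrics, cue_pair)[
        [f"w_emp_normal{sfx}", f"w_emp_noisy{sfx}",
         f"w_pred_normal{sfx}", f"w_pred_noisy{sfx}"]].dropna()
    d_emp = d[f"w_emp_normal{sfx}"] - d[f"w_emp_noisy{sfx}"]
    d_pred = d[f"w_pred_normal{sfx}"] - d[f"w_pred_noisy{sfx}"]
    r_opt = wilcoxon_signed_rank(d_emp.to_numpy(), d_pred.to_numpy())

    w_emp = np.concatenate([d[f"w_emp_normal{sfx}"], d[f"w_emp_noisy{sfx}"]])
    w_pred = np.concatenate([d[f"w_pred_normal{sfx}"], d[f"w_pred_noisy{sfx}"]])
    reg = sps.linregress(w_pred, w_emp)
    t_slope = (reg.slope / reg.stderr) if reg.stderr > 0 else np.inf

    return {
        "weight_drop": MarkerTestResult(f"reweighting-drop[{cue_pair}]",
                                        r_drop.statistic, r_drop.p_value,
                                        r_drop.n, drop_dir, r_drop.method),
        "drop_vs_optimal": MarkerTestResult(f"reweighting-vs-optimal[{cue_pair}]",
                                            r_opt.statistic, r_opt.p_value,
                                            r_opt.n, "", r_opt.method),
        "regression": {"slope": float(reg.slope), "t": float(t_slope),
                       "r": float(reg.rvalue), "p": float(reg.pvalue),
                       "n": int(w_emp.size)},
    }


def test_incongruence(metrics: pd.DataFrame, cue_pair: str = "DS") -> MarkerTestResult:
    """H3: sensory noise under a reversed mapping vs the congruent condition."""
    sfx = f"_{cue_pair}"
    inc, cong = _paired(metrics, cue_pair, f"sigma_inc{sfx}", f"sigma_bi{sfx}")
    if inc.size < MIN_PAIRED:
        raise ValueError(f"need >= {MIN_PAIRED} paired observations, got {inc.size}")
    r = wilcoxon_signed_rank(inc, cong)
    direction = "incongruent noisier" if np.median(inc - cong) > 0 else \
        "incongruent not noisier"
    return MarkerTestResult(f"incongruence[{cue_pair}]", r.statistic, r.p_value,
                            r.n, direction, r.method)


def compare_pairs(metrics: pd.DataFrame, mcnemar_method: str = "chi2-corrected"):
    """H4: marker indices and marker prevalence, familiar vs familiar-novel pair.

    For each marker: paired Wilcoxon on the DS vs DA indices, a both /
    only-DS / only-DA / neither classification (index > 0 counts as present),
    McNemar's test on the discordant cells, and the Pearson correlation between
    the two pairings' indices.
    """
    out = {}
    for marker in ("CI", "RI", "IS"):
        cols = [f"{marker}_DS", f"{marker}_DA"]
        if not all(c in metrics.columns for c in cols):
            continue
        mask = np.ones(len(metrics), dtype=bool)
        for col in ("include_DS", "include_DA"):
            if col in metrics.columns:
                mask &= metrics[col].to_numpy(bool)
        d = metrics.loc[mask, cols].dropna()
        if len(d) < MIN_PAIRED:
            continue
        ds, da = d[cols[0]].to_numpy(float), d[cols[1]].to_numpy(float)
        w = wilcoxon_signed_rank(ds, da)
        present_ds, present_da = ds > 0, da > 0
        counts = {
            "both": int(np.sum(present_ds & present_da)),
            "only_DS": int(np.sum(present_ds & ~present_da)),
            "only_DA": int(np.sum(~present_ds & present_da)),
            "neither": int(np.sum(~present_ds & ~present_da)),
        }
        b, c = counts["only_DS"], counts["only_DA"]
        mcn = (mcnemar_test(b, c, method=mcnemar_method) if b + c > 0 else
               TestResult(float("nan"), float("nan"), 0, "mcnemar/undefined"))
        degenerate = len(d) <= 2 or np.ptp(ds) == 0 or np.ptp(da) == 0
        r, p_r = (np.nan, np.nan) if degenerate else sps.pearsonr(ds, da)
        out[marker] = {
            "wilcoxon": MarkerTestResult(f"{marker}-DS-vs-DA", w.statistic,
                                         w.p_value, w.n,
                                         "DS larger" if np.median(ds - da) > 0
                                         else "DA larger", w.method),
            "classification": counts,
            "mcnemar": MarkerTestResult(f"{marker}-prevalence", mcn.statistic,
                                        mcn.p_value, mcn.n, "", mcn.method),
            "correlation": {"r": float(r), "p": float(p_r), "n": len(d)},
        }
    return out


def nuisance_control(standard, control, paired: bool = True,
                     bf_scale: float = np.sqrt(2) / 2):
    """Control-task comparison: does the standard condition inflate sigma?

    One-sided test of standard > control (signed-rank for the within-observer
    design; ``paired=False`` gives the rank-sum variant) plus a JZS paired-t
    Bayes factor BF01 in favour of no inflation.
    """
    standard = np.asarray(standard, float)
    control = np.asarray(control, float)
    if standard.size < 5 or (paired and control.size != standard.size):
        raise ValueError("need >= 5 paired sigma estimates")
    if paired:
        r = wilcoxon_signed_rank(standard, control, alternative="greater")
        diffs = standard - control
    else:
        r = rank_sum(standard, control, alternative="greater")
        diffs = standard - control.mean()
    bf10 = jzs_bayes_factor(diffs, r=bf_scale)
    return {"test": MarkerTestResult("nuisance-standard>control", r.statistic,
                                     r.p_value, r.n, "", r.method),
            "bf01": 1.0 / bf10, "bf10": bf10}


# ---------------------------------------------------------------------------
# orchestration + report


def analyze_metrics(metrics: pd.DataFrame, fits: pd.DataFrame | None = None,
                    inverse_mapping_participants=()) -> dict:
    """Run exclusions and all group tests; returns a nested results dict."""
    flagged, report = apply_exclusions(metrics, fits,
                                       inverse_mapping_participants)
    results: dict = {"exclusions": report, "metrics": flagged}
    for pair in ("DS", "DA"):
        block: dict = {}
        try:
            block["combination"] = test_combination(flagged, pair)
        except ValueError as err:
            block["combination"] = str(err)
        try:
            block["reweighting"] = test_reweighting(flagged, pair)
        except ValueError as err:
            block["reweighting"] = str(err)
        try:
            block["incongruence"] = test_incongruence(flagged, pair)
        except ValueError as err:
            block["incongruence"] = str(err)
        results[pair] = block
    results["pair_comparison"] = compare_pairs(flagged)
    return results


def _fmt_test(t) -> str:
    if isinstance(t, MarkerTestResult):
        return (f"{t.hypothesis}: stat={t.statistic:.3g}, p={t.p_value:.4g}, "
                f"n={t.n}{', ' + t.direction if t.direction else ''} ({t.method})")
    return str(t)


def render_report(results: dict) -> str:
    """Human-readable markdown report of :func:`analyze_metrics` output."""
    lines = ["# Group analysis report", ""]
    rep: ExclusionReport = results["exclusions"]
    lines.append("## Exclusions")
    if rep.empty:
        lines.append("- none")
    else:
        for _, row in rep.entries.iterrows():
            lines.append(f"- {row['participant']}: {row['rule']} on "
                         f"{row['measure']} (scope: {row['scope']})")
    for pair in ("DS", "DA"):
        lines += ["", f"## Cue pair {pair}"]
        block = results[pair]
        comb = block["combination"]
        if isinstance(comb, tuple):
            lines += [f"- {_fmt_test(comb[0])}", f"- {_fmt_test(comb[1])}"]
        else:
            lines.append(f"- combination: {comb}")
        rw = block["reweighting"]
        if isinstance(rw, dict):
            lines += [f"- {_fmt_test(rw['weight_drop'])}",
                      f"- {_fmt_test(rw['drop_vs_optimal'])}",
                      (f"- regression w_emp ~ w_pred: slope="
                       f"{rw['regression']['slope']:.3f}, r={rw['regression']['r']:.3f}, "
                       f"p={rw['regression']['p']:.4g}")]
        else:
            lines.append(f"- reweighting: {rw}")
        lines.append(f"- {_fmt_test(block['incongruence'])}")
    lines += ["", "## Cue-pair differences"]
    for marker, res in results["pair_comparison"].items():
        c = res["classification"]
        lines += [
            f"### {marker}",
            f"- {_fmt_test(res['wilcoxon'])}",
            (f"- classification: both={c['both']}, only_DS={c['only_DS']}, "
             f"only_DA={c['only_DA']}, neither={c['neither']}"),
            f"- {_fmt_test(res['mcnemar'])}",
            f"- correlation DS~DA: r={res['correlation']['r']:.3f}, "
            f"p={res['correlation']['p']:.4g}",
        ]
    return "\n".join(lines) + "\n"
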