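"""Statistical primitives used by the group-level analyses.

Thin, convention-pinning wrappers: Wilcoxon signed-rank (zeros discarded, exact
null for n <= 25 without ties, else normal approximation with continuity
correction), McNemar's test for paired dichotomous outcomes
(continuity-corrected chi-square by default, exact binomial optionally), and a
default-prior JZS paired-t Bayes factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "wilcoxon_signed_rank", "rank_sum", "mcnemar_test",
           "jzs_bayes_factor"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    alternative: str = "two-sided"


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired data (or precomputed differences).

    Zero differences are discarded (Wilcoxon's convention).  The exact null
    distribution is used for n < 50 when |differences| are untied (the
    convention of R's wilcox.test, the toolchain such studies are analysed
    with); otherwise the normal approximation with continuity correction.
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, n=0, method="degenerate",
                          alternative=alternative)
    ties = np.unique(np.abs(d)).size < n
    if n < 50 and not ties:
        method = "exact"
        res = sps.wilcoxon(d, alternative=alternative, method="exact")
    else:
        method = "normal-approx"
        res = sps.wilcoxon(d, alternative=alternative, method="approx",
                           correction=True)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n=n, method=f"wilcoxon-signed-rank/{method}",
                      alternative=alternative)


def rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test for two independent samples."""
    res = sps.mannwhitneyu(np.asarray(x, float), np.asarray(y, float),
                           alternative=alternative)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n=len(x) + len(y), method="rank-sum", alternative=alternative)


def mcnemar_test(b: int, c: int, method: str = "chi2-corrected") -> TestResult:
    """McNemar's test from the two discordant cell counts.

    ``b`` and ``c`` count the participants showing the effect in only the first
    or only the second pairing.  ``chi2-corrected`` uses the continuity-corrected
    statistic (|b - c| - 1)^2 / (b + c) against chi-square(1); ``exact`` uses the
    two-sided binomial(b + c, 1/2) distribution of b.
    """
    b, c = int(b), int(c)
    m = b + c
    if m == 0:
        return TestResult(statistic=float("nan"), p_value=float("nan"), n=0,
                          method="mcnemar/undefined")
    if method == "chi2-corrected":
        stat = (abs(b - c) - 1) ** 2 / m if abs(b - c) > 1 else 0.0
        p = float(sps.chi2.sf(stat, df=1))
        return TestResult(statistic=float(stat), p_value=p, n=m,
                          method="mcnemar/chi2-corrected")
    if method == "exact":
        k = min(b, c)
        p = min(1.0, 2.0 * float(sps.binom.cdf(k, m, 0.5))
                - (float(sps.binom.pmf(k, m, 0.5)) if b == c else 0.0))
        # two-sided exact: double the smaller tail, capped at 1
        return TestResult(statistic=float(min(b, c)), p_value=min(p, 1.0), n=m,
                          method="mcnemar/exact")
    raise ValueError(f"unknown method {method!r}")


def jzs_bayes_factor(diffs, r: float = np.sqrt(2) / 2) -> float:
    """JZS (Cauchy-prior) Bayes factor BF10 for a one-sample/paired t design.

    ``r`` is the Cauchy scale on the standardised effect (default sqrt(2)/2).
    Returns BF10; BF01 in favour of the null is its reciprocal.
    """
    from pingouin import bayesfactor_ttest

    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 differences")
    t = float(d.mean() / (d.std(ddof=1) / np.sqrt(n)))
    return float(bayesfactor_ttest(t, n, paired=True, r=r))
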