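"""Exclusion rules and group-level marker tests."""

import numpy as np
import pandas as pd
import pytest

from cuecombine.group import (apply_exclusions, compare_pairs,
                              detect_inverse_mapping, iqr_fence_outliers,
                              nuisance_control)
from cuecombine.group import test_combination as combination_tests
from cuecombine.group import test_incongruence as incongruence_test
from cuecombine.group import test_reweighting as reweighting_tests


def _metrics_frame(n, rng, combine=True, seed_shift=0.0):
    """Synthetic per-participant metrics with plausible fitting scatter."""
    s_d = 0.2 + rng.normal(0, 0.02, n)
    s_s = 0.3 + rng.normal(0, 0.03, n)
    s_opt = np.sqrt(s_d ** 2 * s_s ** 2 / (s_d ** 2 + s_s ** 2))
    s_bi = (s_opt if combine else np.minimum(s_d, s_s)) + rng.normal(0, 0.02, n)
    df = pd.DataFrame({
        "participant": [f"p{i}" for i in range(n)],
        "sigma_D_DS": s_d, "sigma_S_DS": s_s, "sigma_bi_DS": s_bi,
        "sigma_opt_DS": s_opt,
        "sigma_inc_DS": s_bi + 0.08 + rng.normal(0, 0.02, n),
        "w_emp_normal_DS": 0.7 + rng.normal(0, 0.05, n),
        "w_emp_noisy_DS": 0.4 + rng.normal(0, 0.05, n),
        "w_pred_normal_DS": 0.7 + rng.normal(0, 0.03, n),
        "w_pred_noisy_DS": 0.4 + rng.normal(0, 0.03, n),
    })
    df["CI_DS"] = np.minimum(s_d, s_s) - s_bi
    df["RI_DS"] = df["w_emp_normal_DS"] - df["w_emp_noisy_DS"]
    df["IS_DS"] = df["sigma_inc_DS"] - df["sigma_bi_DS"]
    return df


class TestExclusions:
    def test_fence_flags_extreme_noise(self):
        vals = pd.Series([0.2, 0.21, 0.22, 0.23, 5.0])
        out = iqr_fence_outliers(vals)
        # median 0.22, IQR 0.02 -> fence 0.05; only the 5.0 observer is out
        assert list(out) == [False, False, False, False, True]

    def test_identical_values_exclude_nothing(self):
        assert not iqr_fence_outliers(pd.Series([0.3] * 6)).any()

    def test_high_lapse_excluded_everywhere(self, rng):
        metrics = _metrics_frame(8, rng)
        fits = pd.DataFrame({
            "participant": np.repeat([f"p{i}" for i in range(8)], 2),
            "session": [2, 4] * 8,
            "lambda": [0.02] * 14 + [0.12, 0.13],
        })
        flagged, report = apply_exclusions(metrics, fits)
        assert "p7" in report.excluded("DS") and "p7" in report.excluded("DA")
        assert not flagged.loc[flagged["participant"] == "p7", "include_DS"].iloc[0]
        rules = report.entries.set_index("participant")["rule"]
        assert rules["p7"] == "lapse>=0.10"

    def test_disparity_fence_is_global_size_fence_is_pairwise(self, rng):
        metrics = _metrics_frame(8, rng)
        metrics["sigma_D_DA"] = metrics["sigma_D_DS"]
        metrics["sigma_A_DA"] = 0.3 + rng.normal(0, 0.01, 8)
        metrics.loc[0, "sigma_D_DS"] = 6.0   # unusable disparity: all analyses
        metrics.loc[1, "sigma_S_DS"] = 7.0   # unusable size: DS pair only
        flagged, report = apply_exclusions(metrics)
        assert report.excluded("DS") >= {"p0", "p1"}
        assert "p0" in report.excluded("DA") and "p1" not in report.excluded("DA")

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_exclusions(_metrics_frame(3, rng))


class TestInverseMappingDetection:
    def test_flips_are_detected(self, rng):
        from cuecombine.design import ConditionSpec
        from cuecombine.observers import ObserverProfile, simulate_trials
        obs = ObserverProfile(sigma_A=0.25)
        good = simulate_trials(obs, ConditionSpec(("A",)), n_reps=10, seed=1,
                               participant="good", condition_label="A")
        bad = simulate_trials(obs, ConditionSpec(("A",)), n_reps=10, seed=2,
                              participant="bad", condition_label="A")
        bad["response"] = 1 - bad["response"]
        found = detect_inverse_mapping(pd.concat([good, bad]))
        assert found == ["bad"]


class TestMarkerTests:
    def test_combining_group_detected(self, rng):
        metrics = _metrics_frame(40, rng, combine=True)
        vs_best, vs_opt = combination_tests(metrics, "DS")
        assert vs_best.p_value < 0.05 and vs_best.direction == "bimodal lower"
        assert vs_opt.p_value > 0.05

    def test_best_single_cue_group_complementary(self, rng):
        metrics = _metrics_frame(40, rng, combine=False)
        vs_best, vs_opt = combination_tests(metrics, "DS")
        assert vs_best.p_value > 0.05
        assert vs_opt.p_value < 0.05 and vs_opt.direction == "above optimal"

    def test_reweighting_detected_and_regression_identity(self, rng):
        metrics = _metrics_frame(30, rng)
        res = reweighting_tests(metrics, "DS")
        assert res["weight_drop"].p_value < 0.05
        assert res["weight_drop"].direction == "weight drops"
        # w_emp == w_pred exactly: slope 1, r = 1, vs-optimal p = 1
        ident = metrics.copy()
        ident["w_emp_normal_DS"] = ident["w_pred_normal_DS"]
        ident["w_emp_noisy_DS"] = ident["w_pred_noisy_DS"]
        res2 = reweighting_tests(ident, "DS")
        assert res2["regression"]["slope"] == pytest.approx(1.0, abs=1e-9)
        assert res2["regression"]["r"] == pytest.approx(1.0, abs=1e-9)
        assert res2["drop_vs_optimal"].p_value == 1.0

    def test_incongruence_detected(self, rng):
        metrics = _metrics_frame(30, rng)
        res = incongruence_test(metrics, "DS")
        assert res.p_value < 0.05 and res.direction == "incongruent noisier"

    def test_too_few_participants_refused(self, rng):
        metrics = _metrics_frame(5, rng)
        with pytest.raises(ValueError):
            combination_tests(metrics, "DS")


class TestComparePairs:
    def _two_pair_metrics(self, rng, n=40):
        m = _metrics_frame(n, rng)
        m["CI_DA"] = m["CI_DS"] - 0.04 + rng.normal(0, 0.02, n)
        m["RI_DA"] = m["RI_DS"] + rng.normal(0, 0.05, n)
        m["IS_DA"] = m["IS_DS"] + rng.normal(0, 0.02, n)
        return m

    def test_classification_partition(self, rng):
        m = self._two_pair_metrics(rng)
        res = compare_pairs(m)
        for marker, r in res.items():
            c = r["classification"]
            assert sum(c.values()) == 40

    def test_all_combiners_mcnemar_undefined(self, rng):
        m = self._two_pair_metrics(rng)
        m["CI_DS"] = 0.1
        m["CI_DA"] = 0.1
        res = compare_pairs(m)
        assert "undefined" in res["CI"]["mcnemar"].method

    def test_prevalence_difference_detected(self, rng):
        """DS-only combiners far outnumber DA-only: McNemar significant."""
        n = 60
        m = self._two_pair_metrics(rng, n)
        m["CI_DS"] = np.abs(m["CI_DS"]) + 0.02       # everyone combines DS
        da = np.where(np.arange(n) < 24, 0.05, -0.05)  # 40% combine DA
        m["CI_DA"] = da
        res = compare_pairs(m)
        assert res["CI"]["mcnemar"].p_value < 0.05


class TestNuisanceControl:
    def test_identical_conditions_favour_null(self, rng):
        sig = 0.25 + rng.normal(0, 0.02, 12)
        res = nuisance_control(sig, sig + rng.normal(0, 0.01, 12))
        assert res["test"].p_value > 0.2
        assert res["bf01"] > 1.0

    def test_inflation_detected_often_enough(self):
        """1.5x noise inflation at n = 12: one-sided p < 0.05 in >= 60% of
        replicates; no inflation: BF01 > 3 in the majority."""
        rng = np.random.default_rng(99)
        hits = 0
        bf_null = 0
        reps = 200
        for _ in range(reps):
            control = 0.2 + np.abs(rng.normal(0, 0.03, 12))
            standard = control * 1.5 + rng.normal(0, 0.02, 12)
            if nuisance_control(standard, control)["test"].p_value < 0.05:
                hits += 1
            null_std = control + rng.normal(0, 0.01, 12)
            if nuisance_control(null_std, control)["bf01"] > 3.0:
                bf_null += 1
        assert hits / reps >= 0.60
        assert bf_null / reps > 0.50

    def test_refuses_small_samples(self):
        with pytest.raises(ValueError):
            nuisance_control([0.2] * 4, [0.2] * 4)
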