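"""Generative observer model: response probabilities, strategies, trial tables."""

import numpy as np
import pytest

from cuecombine.design import ConditionSpec, DepthDesign
from cuecombine.metrics import optimal_sigma, predicted_weight
from cuecombine.observers import (DEFAULT_SESSION_SCHEDULE, ObserverProfile,
                                  PopulationSpec, percept_sample,
                                  response_probability, simulate_study,
                                  simulate_trials)
from cuecombine.psychofit import psi


def _empirical_sigma(obs, spec, n=200_000, seed=0):
    """Single-interval effective noise from simulated percept differences."""
    rng = np.random.default_rng(seed)
    r, c = percept_sample(np.zeros(n), spec, obs, rng)
    return np.std(c - r) / np.sqrt(2.0)


class TestResponseProbability:
    def test_matches_psychometric_function(self, levels, rng):
        """Simulated response proportions follow psi with beta = 1/(sigma*sqrt2)."""
        obs = ObserverProfile(sigma_D=0.25, lapse=0.08)
        spec = ConditionSpec(("D",))
        p_analytic = response_probability(levels, spec, obs)
        beta = 1.0 / (0.25 * np.sqrt(2.0))
        assert np.allclose(p_analytic, psi(levels, 0.0, beta, 0.08))
        # trial-level simulator agrees within binomial error
        n_rep = 4000
        trials = simulate_trials(obs, spec, DepthDesign(easy_trial_rate=0.0),
                                 n_reps=n_rep, seed=rng)
        from cuecombine.psychofit import counts_from_trials
        lv, k, n = counts_from_trials(trials)     # sorted by level
        p_sorted = response_probability(lv, spec, obs)
        se = np.sqrt(p_sorted * (1 - p_sorted) / n_rep)
        assert np.all(np.abs(k / n - p_sorted) < 4 * se + 1e-9)

    def test_optimal_fusion_noise_matches_prediction(self):
        obs = ObserverProfile(sigma_D=0.2, sigma_S=0.3, strategy="optimal")
        spec = ConditionSpec(("D", "S"))
        sim = _empirical_sigma(obs, spec)
        assert sim == pytest.approx(optimal_sigma(0.2, 0.3).sigma_opt, rel=0.02)

    def test_equal_noise_fusion_gives_sigma_over_sqrt2(self):
        obs = ObserverProfile(sigma_D=0.3, sigma_S=0.3)
        sim = _empirical_sigma(obs, ConditionSpec(("D", "S")))
        assert sim == pytest.approx(0.3 / np.sqrt(2.0), rel=0.02)

    def test_best_single_cue_uses_min_sigma(self):
        obs = ObserverProfile(sigma_D=0.2, sigma_S=0.3, strategy="best-single")
        sim = _empirical_sigma(obs, ConditionSpec(("D", "S")))
        assert sim == pytest.approx(0.2, rel=0.02)

    def test_switching_exceeds_best_single_cue(self):
        obs = ObserverProfile(sigma_D=0.2, sigma_S=0.2, strategy="switching",
                              switch_p=0.5)
        sim = _empirical_sigma(obs, ConditionSpec(("D", "S")))
        assert sim > 0.2  # mixture variance: no fusion benefit

    def test_noisy_disparity_inflates_sigma(self):
        obs = ObserverProfile(sigma_D=0.2)
        assert obs.sigma_for("D", noisy=True) == pytest.approx(0.4)
        p_clean = response_probability(0.3, ConditionSpec(("D",)), obs)
        p_noisy = response_probability(0.3, ConditionSpec(("D",), disparity_noisy=True), obs)
        assert p_noisy < p_clean  # shallower psychometric function


class TestConflict:
    def test_disparity_dominant_observer_ignores_conflict(self, levels):
        """With sigma_S -> infinity-like, the PSE shift vanishes."""
        obs = ObserverProfile(sigma_D=0.2, sigma_S=50.0)
        spec = ConditionSpec(("D", "S"), conflict_delta=0.3)
        p = response_probability(levels, spec, obs)
        p0 = response_probability(levels, ConditionSpec(("D", "S")), obs)
        assert np.allclose(p, p0, atol=2e-3)

    def test_equal_noise_conflict_shifts_pse_by_half_delta(self):
        """sigma_D = sigma_S: expected PSE shift = delta / 2 (w = 0.5)."""
        delta = 0.4
        obs = ObserverProfile(sigma_D=0.25, sigma_S=0.25)
        spec = ConditionSpec(("D", "S"), conflict_delta=delta)
        # P(further) = 0.5 exactly at x = delta/2
        assert response_probability(delta / 2.0, spec, obs) == pytest.approx(0.5)
        # and by brute-force simulation of 1e5 percept pairs
        rng = np.random.default_rng(7)
        r, c = percept_sample(np.full(100_000, delta / 2.0), spec, obs, rng)
        assert np.mean(c > r) == pytest.approx(0.5, abs=0.006)

    def test_general_shift_is_one_minus_weight_times_delta(self):
        delta = 0.3
        obs = ObserverProfile(sigma_D=0.2, sigma_S=0.4)
        w_d = predicted_weight(0.2, 0.4)
        spec = ConditionSpec(("D", "S"), conflict_delta=delta)
        shift = (1 - w_d) * delta
        assert response_probability(shift, spec, obs) == pytest.approx(0.5)


class TestIncongruence:
    def test_fusing_observer_loses_precision(self):
        obs = ObserverProfile(sigma_D=0.2, sigma_S=0.3)
        cong = _empirical_sigma(obs, ConditionSpec(("D", "S")), seed=1)
        # incongruence shrinks the effective slope: estimate sigma from the
        # response probability at a fixed level instead of percept spread
        spec_i = ConditionSpec(("D", "S"), incongruent=True)
        p_cong = response_probability(0.3, ConditionSpec(("D", "S")), obs)
        p_inc = response_probability(0.3, spec_i, obs)
        assert p_inc < p_cong
        assert cong == pytest.approx(optimal_sigma(0.2, 0.3).sigma_opt, rel=0.03)

    def test_best_single_cue_observer_unaffected(self, levels):
        obs = ObserverProfile(sigma_D=0.2, sigma_S=0.3, strategy="best-single")
        p_c = response_probability(levels, ConditionSpec(("D", "S")), obs)
        p_i = response_probability(levels, ConditionSpec(("D", "S"), incongruent=True), obs)
        assert np.allclose(p_c, p_i)

    def test_unbound_novel_cue_is_not_fused(self, levels):
        obs = ObserverProfile(sigma_D=0.2, sigma_A=0.3, binds_novel_cue=False)
        p_da = response_probability(levels, ConditionSpec(("D", "A")), obs)
        p_d = response_probability(levels, ConditionSpec(("D",)), obs)
        assert np.allclose(p_da, p_d)


class TestSimulateTrials:
    def test_row_counts(self):
        obs = ObserverProfile()
        t = simulate_trials(obs, ConditionSpec(("D",)), n_reps=12, seed=0)
        assert (~t["easy"]).sum() == 168  # 14 levels x 12 reps
        assert t["easy"].sum() == DepthDesign().n_easy(168)

    def test_total_trials_distributed_over_levels(self):
        obs = ObserverProfile()
        t = simulate_trials(obs, ConditionSpec(("D",)), n_reps=None,
                            n_trials=150, seed=0)
        main = t[~t["easy"]]
        assert len(main) == 150
        counts = main.groupby("comparison_level").size()
        assert set(counts) <= {10, 11} and len(counts) == 14

    def test_full_lapse_forces_further_responses(self):
        """lapse = 1 makes every recoded response 'comparison further'."""
        obs = ObserverProfile(lapse=1.0)
        t = simulate_trials(obs, ConditionSpec(("D",)), n_reps=5, seed=3)
        from cuecombine.psychofit import recode_responses
        assert np.all(recode_responses(t) == 1)
        # raw responses depend on the interval order, so both codes appear
        assert set(t["response"]) == {0, 1}

    def test_near_deterministic_observer(self):
        obs = ObserverProfile(sigma_D=1e-4, sigma_S=1e-4, lapse=0.0)
        t = simulate_trials(obs, ConditionSpec(("D",)), n_reps=12, seed=4)
        from cuecombine.psychofit import recode_responses
        main = t[~t["easy"]]
        assert np.array_equal(recode_responses(main),
                              (main["comparison_level"] > 0).astype(int))

    def test_seed_reproducibility(self):
        obs = ObserverProfile()
        a = simulate_trials(obs, ConditionSpec(("D", "S")), n_reps=12, seed=11)
        b = simulate_trials(obs, ConditionSpec(("D", "S")), n_reps=12, seed=11)
        assert a.equals(b)


class TestSimulateStudy:
    def test_structure_and_determinism(self):
        pop = PopulationSpec(n_participants=2, within_sd=0.0)
        t = simulate_study(pop, sessions={2: ["D", "DS"], 4: ["D", "DS"]},
                           n_trials_per_condition=56, seed=5)
        assert set(t["session"]) == {2, 4}
        per = t.groupby(["participant", "session", "condition"]).size()
        assert (per >= 56).all()  # main trials plus easy trials
        # mapping direction counterbalanced
        dirs = t.groupby("participant")["mapping_direction"].first()
        assert set(dirs) == {1, -1}
        t2 = simulate_study(pop, sessions={2: ["D", "DS"], 4: ["D", "DS"]},
                            n_trials_per_condition=56, seed=5)
        assert t.equals(t2)

    def test_default_schedule_covers_study_sessions(self):
        assert set(DEFAULT_SESSION_SCHEDULE) == {2, 3, 4}
        assert {"D", "S", "A", "DS", "DA"} <= set(DEFAULT_SESSION_SCHEDULE[2])
        assert {"Du", "DuS", "DuA"} <= set(DEFAULT_SESSION_SCHEDULE[3])
        assert {"DSi", "DAi"} <= set(DEFAULT_SESSION_SCHEDULE[4])
        assert any(c.endswith("+") for c in DEFAULT_SESSION_SCHEDULE[2])
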