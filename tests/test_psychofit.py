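"""Two-stage psychometric fitting: recovery, invariances, numerics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import norm

from cuecombine.design import ConditionSpec, DepthDesign
from cuecombine.observers import ObserverProfile, simulate_trials
from cuecombine.psychofit import (GridSpec, PsychometricModel,
                                  counts_from_trials, fit_beta_grid,
                                  fit_condition, fit_lapse_grid,
                                  fit_shared_lapse, fit_trial_table, psi,
                                  recode_responses)

S2 = np.sqrt(2.0)


class TestPsi:
    def test_midpoint(self):
        assert psi(0.3, 0.3, 5.0, 0.0) == pytest.approx(0.5)

    def test_midpoint_with_lapse(self):
        lam = 0.1
        assert psi(0.0, 0.0, 5.0, lam) == pytest.approx(lam + (1 - lam) / 2)

    def test_asymptotes_as_printed(self):
        assert psi(-50.0, 0.0, 5.0, 0.07) == pytest.approx(0.07, abs=1e-12)
        assert psi(50.0, 0.0, 5.0, 0.07) == pytest.approx(1.0, abs=1e-12)

    def test_one_jnd_above_pse(self):
        """x = alpha + 1/beta gives Phi(1) ~ 0.8413 without lapses."""
        assert psi(0.2 + 1 / 4.0, 0.2, 4.0, 0.0) == pytest.approx(
            norm.cdf(1.0), abs=1e-12)

    def test_monotone_nondecreasing(self):
        x = np.linspace(-1, 1, 101)
        p = psi(x, 0.1, 3.0, 0.05)
        assert np.all(np.diff(p) >= 0)

    def test_model_dataclass_validation(self):
        with pytest.raises(ValueError):
            PsychometricModel(alpha=0.0, beta=-1.0, lam=0.0)
        with pytest.raises(ValueError):
            PsychometricModel(alpha=0.0, beta=1.0, lam=1.5)


def _binomial_counts(rng, sigma, lam, levels, n_reps=12):
    """Binomial counts of shape sigma.shape + (len(levels),)."""
    sigma = np.asarray(sigma, dtype=float)
    p = lam + (1 - lam) * ndtr(levels / (sigma[..., None] * S2))
    k = rng.binomial(n_reps, p).astype(float)
    return k, np.full(k.shape, float(n_reps))


class TestSharedLapse:
    def test_lapse_recovery_across_replicates(self, levels, rng):
        """lambda = 0.05 over 5 conditions x 168 trials: recovered within 0.03."""
        true_lam = 0.05
        sigmas = np.array([0.2, 0.25, 0.3, 0.18, 0.22])
        n_rep_study = 100
        k, n = _binomial_counts(rng, np.tile(sigmas, (n_rep_study, 1)), true_lam,
                                levels)
        lam_hat = fit_lapse_grid(k, n, levels)
        err = np.abs(lam_hat - true_lam)
        assert np.median(err) < 0.03

    def test_zero_lapse_data_gives_small_estimate(self, levels, rng):
        sigmas = np.array([0.2, 0.25, 0.3, 0.18, 0.22])
        k, n = _binomial_counts(rng, np.tile(sigmas, (20, 1)), 0.0, levels)
        lam_hat = fit_lapse_grid(k, n, levels)
        assert np.median(lam_hat) <= 0.02

    def test_estimate_respects_bounds(self, levels, rng):
        # heavy lapsing: estimate saturates at the 0.2 bound, never beyond
        k, n = _binomial_counts(rng, np.full((10, 3), 0.2), 0.4, levels)
        lam_hat = fit_lapse_grid(k, n, levels)
        assert np.all((lam_hat >= 0.0) & (lam_hat <= 0.2))

    def test_table_api_needs_two_conditions(self):
        obs = ObserverProfile()
        t = simulate_trials(obs, ConditionSpec(("D",)), n_reps=12, seed=0)
        with pytest.raises(ValueError):
            fit_shared_lapse(t)


class TestConditionFit:
    def test_slope_recovery_median_relative_error(self, levels, rng):
        """beta = 5, lambda = 0.02, 168 trials: median |rel err| < 20%."""
        sigma = 1 / (5.0 * S2)
        k, n = _binomial_counts(rng, np.full((100, 1), sigma), 0.02, levels)
        res = fit_beta_grid(k, n, levels, np.full(100, 0.02))
        rel = np.abs(res["beta"][:, 0] - 5.0) / 5.0
        assert np.median(rel) < 0.20

    def test_conflict_pse_recovery(self, rng):
        """True PSE = 0.3 * delta recovered within 0.1 * delta (median)."""
        delta = 0.3
        obs = ObserverProfile(sigma_D=0.2, sigma_S=0.2 * np.sqrt(7 / 3), lapse=0.02)
        # choose sigma_S so that w_D = 0.7 -> PSE = 0.3 * delta
        spec = ConditionSpec(("D", "S"), conflict_delta=delta)
        errs = []
        for i in range(40):
            t = simulate_trials(obs, spec, n_reps=12, seed=rng)
            fit = fit_condition(t, lam=0.02, alpha_free=True)
            errs.append(abs(fit.model.alpha - 0.3 * delta))
        assert np.median(errs) < 0.1 * delta

    def test_refuses_tiny_tables(self):
        obs = ObserverProfile()
        t = simulate_trials(obs, ConditionSpec(("D",)), n_reps=1, seed=0)
        with pytest.raises(ValueError, match="refusing"):
            fit_condition(t.head(14), lam=0.02)

    def test_separable_data_flags_boundary(self):
        """A perfect 0/1 step forces beta to the top of its range."""
        x = np.repeat([-1.0, -0.5, 0.5, 1.0], 30)
        df = pd.DataFrame({"participant": "p", "session": 2, "condition": "D",
                           "comparison_level": x, "easy": False,
                           "response": (x > 0).astype(int)})
        fit = fit_condition(df, lam=0.0)
        assert "boundary" in fit.flags and not fit.converged
        assert fit.model.beta > 50

    def test_row_order_and_interval_relabel_invariance(self, rng):
        obs = ObserverProfile(sigma_D=0.25, lapse=0.03)
        t = simulate_trials(obs, ConditionSpec(("D",)), n_reps=12, seed=9)
        f1 = fit_condition(t, lam=0.03)
        shuffled = t.sample(frac=1.0, random_state=1)
        f2 = fit_condition(shuffled, lam=0.03)
        # relabel interval order: flip reference_interval and raw response
        flipped = t.copy()
        flipped["reference_interval"] = 3 - flipped["reference_interval"]
        flipped["response"] = 1 - flipped["response"]
        f3 = fit_condition(flipped, lam=0.03)
        assert f1.model.beta == pytest.approx(f2.model.beta, abs=1e-12)
        assert f1.model.beta == pytest.approx(f3.model.beta, abs=1e-12)

    def test_grid_refinement_changes_beta_under_one_percent(self, rng):
        obs = ObserverProfile(sigma_D=0.25, lapse=0.02)
        t = simulate_trials(obs, ConditionSpec(("D",)), n_reps=12, seed=21)
        base = GridSpec()
        fine = base.refined(2)
        b1 = fit_condition(t, lam=0.02, grid=base).model.beta
        b2 = fit_condition(t, lam=0.02, grid=fine).model.beta
        assert abs(b2 - b1) / b1 < 0.01


class TestTwoStageRationale:
    def test_fixed_lapse_beats_free_lapse_rmse(self, levels, rng):
        """Fixing lambda at truth lowers the RMSE of beta vs per-condition
        free-lambda fits (the motivation for the shared-lapse stage)."""
        true_lam, sigma = 0.06, 0.25
        beta_true = 1 / (sigma * S2)
        k, n = _binomial_counts(rng, np.full((100, 1), sigma), true_lam, levels)
        fixed = fit_beta_grid(k, n, levels, np.full(100, true_lam))["beta"][:, 0]
        # free lambda: marginalise over the lambda grid per condition
        from cuecombine.psychofit import fit_single_stage_grid
        free = fit_single_stage_grid(k, n, levels, alpha_free=False)["beta"][:, 0]
        rmse_fixed = np.sqrt(np.mean((fixed - beta_true) ** 2))
        rmse_free = np.sqrt(np.mean((free - beta_true) ** 2))
        assert rmse_fixed < rmse_free

    def test_local_optimality_of_map(self, levels, rng):
        """Perturbing any parameter away from the grid MAP lowers the Bernoulli
        log-likelihood on the fitted data."""
        obs = ObserverProfile(sigma_D=0.25, lapse=0.04)
        t = simulate_trials(obs, ConditionSpec(("D",)), n_reps=12, seed=13)
        lv, k, n = counts_from_trials(t)

        def loglik(alpha, beta, lam):
            p = np.clip(psi(lv, alpha, beta, lam), 1e-12, 1 - 1e-12)
            return np.sum(k * np.log(p) + (n - k) * np.log(1 - p))

        # locate the grid MAP over (beta, lambda)
        grid = GridSpec()
        ll = np.array([[loglik(0.0, b, l) for l in grid.lam] for b in grid.beta])
        bi, li = np.unravel_index(np.argmax(ll), ll.shape)
        b0, l0 = grid.beta[bi], grid.lam[li]
        base = loglik(0.0, b0, l0)
        for db, dl in ((0.2, 0.0), (-0.2, 0.0), (0.0, 0.02), (0.0, -0.02)):
            if 0 <= l0 + dl <= 0.2 and b0 + db > 0:
                assert loglik(0.0, b0 + db, l0 + dl) <= base + 1e-9


class TestTrialTableFit:
    def test_full_two_stage_over_participants(self, rng):
        obs = ObserverProfile(sigma_D=0.2, sigma_S=0.3, lapse=0.04)
        frames = []
        for label, spec in (("D", ConditionSpec(("D",))),
                            ("S", ConditionSpec(("S",))),
                            ("DS", ConditionSpec(("D", "S")))):
            frames.append(simulate_trials(obs, spec, n_reps=12, seed=rng,
                                          participant="p1", session=2,
                                          condition_label=label))
        fits = fit_trial_table(pd.concat(frames))
        assert len(fits) == 3
        assert fits["lambda"].nunique() == 1  # shared within participant-session
        assert (fits["alpha_fixed"]).all()
        sig = 1 / (fits.set_index("condition")["beta"] * S2)
        assert sig["DS"] < sig["S"]

    def test_recode_responses_roundtrip(self, rng):
        obs = ObserverProfile(sigma_D=0.2)
        t = simulate_trials(obs, ConditionSpec(("D",)), n_reps=6, seed=2)
        comp = recode_responses(t)
        raw = np.where(t["reference_interval"] == 1, comp, 1 - comp)
        assert np.array_equal(raw, t["response"].to_numpy())
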