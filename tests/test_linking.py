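"""Probit readout model: probabilities, fitting, noise interpretation, JNDs."""

import dataclasses

import numpy as np
import pytest

import neuroreadout as nr
from neuroreadout.linking import TASKS
from neuroreadout.response import PopulationResponseFunction
from neuroreadout.stimuli import Stimulus, TrialRecord

from conftest import simulate_flexible_trials


def make_trial(con_l, coh_l, con_r, coh_r, task="contrast", **kw):
    return TrialRecord(
        trial_id=0, run_id=0, task=task,
        left=Stimulus(con_l, coh_l), right=Stimulus(con_r, coh_r),
        target_side_con="right", target_side_coh="right",
        delta_con=0.0, delta_coh=0.0, **kw,
    )


def linear_coherence_prf(slope=2.0):
    """Near-linear coherence channel: response ~ slope * s_coh."""
    kappa = 50.0
    alpha = nr.response.alpha_coh_for_slope(slope, kappa)
    return {"A": PopulationResponseFunction("A", 0.0, 0.5, alpha, kappa)}


def single_area_model(weight=1.0, **kw):
    return nr.ReadoutModel(
        areas=("A",),
        weights={"contrast": {"A": weight}, "coherence": {"A": weight}},
        readout_mode="fixed", **kw,
    )


class TestChoiceProbability:
    def test_identical_stimuli_give_half(self, prf_two_area, truth_two_area):
        model = dataclasses.replace(truth_two_area, beta_bias=0.0, lapse=0.0)
        t = make_trial(0.4, 0.3, 0.4, 0.3)
        assert nr.choice_probability(model, prf_two_area, t) == pytest.approx(0.5)

    def test_full_lapse_gives_half_everywhere(self, prf_two_area, truth_two_area):
        model = dataclasses.replace(truth_two_area, lapse=1.0)
        t = make_trial(0.3, 0.0, 0.9, 0.6)
        assert nr.choice_probability(model, prf_two_area, t) == pytest.approx(0.5)

    def test_invalid_lapse_rejected(self, truth_two_area):
        with pytest.raises(ValueError):
            dataclasses.replace(truth_two_area, lapse=1.5)

    @pytest.mark.parametrize("noise_mode,selection_rho,history", [
        ("additive", None, None),
        ("additive", 2.0, None),
        ("additive", None, "on"),
        ("poisson", None, None),
    ])
    def test_matches_monte_carlo_oracle(self, prf_two_area, noise_mode, selection_rho, history, seed=5):
        """The analytic P(right) equals the fraction of 10^6 draws of the
        noisy decision variable that favour right, within 3 MC SE."""
        rng = np.random.default_rng(seed)
        n_draws = 1_000_000
        for point in range(5):
            w = {t: {a: rng.uniform(-3, 8) for a in ("V1", "MT")} for t in TASKS}
            hist = (
                None if history is None
                else dict(zip(("left_correct", "right_correct", "left_incorrect", "right_incorrect"),
                              rng.uniform(-1, 1, 4)))
            )
            model = nr.ReadoutModel(
                areas=("V1", "MT"), weights=w, beta_bias=rng.uniform(-1, 1),
                lapse=rng.uniform(0, 0.2), noise_mode=noise_mode,
                selection_rho=selection_rho, history=hist,
            )
            trial = make_trial(*rng.uniform(0.1, 0.9, 4), prev_choice="left", prev_correct=True)
            p_analytic = nr.choice_probability(model, prf_two_area, trial)

            # draw the decision variable by brute force
            r_l = np.array([prf_two_area[a].response(trial.left.contrast, trial.left.coherence)
                            for a in model.areas])
            r_r = np.array([prf_two_area[a].response(trial.right.contrast, trial.right.coherence)
                            for a in model.areas])
            wv = model.weight_vector("contrast")
            if selection_rho:
                sp = lambda x, p: np.sign(x) * np.abs(x) ** p
                u = sp(r_r, selection_rho) @ wv - sp(r_l, selection_rho) @ wv + model.beta_bias
                z = sp(u, 1 / selection_rho)
                sigma = 1.0
            else:
                z = (r_r - r_l) @ wv + model.beta_bias
                if hist is not None:
                    z += hist["left_correct"]
                sigma = 1.0
                if noise_mode == "poisson":
                    sigma = np.sqrt(0.5 * (r_l.mean() + r_r.mean()))
            noise = rng.normal(0, sigma, n_draws)
            p_core = np.mean(z + noise > 0)
            lapse_flip = rng.random(n_draws) < model.lapse
            right = np.where(lapse_flip, rng.random(n_draws) < 0.5, z + noise > 0)
            p_mc = right.mean()
            se = np.sqrt(p_mc * (1 - p_mc) / n_draws)
            assert abs(p_analytic - p_mc) < 3 * se + 1e-4

    def test_probabilities_bounded_by_lapse(self, prf_two_area, truth_two_area, behavior_4000):
        model = dataclasses.replace(truth_two_area, lapse=0.1)
        p = nr.choice_probabilities(model, prf_two_area, behavior_4000)
        assert np.all(p >= 0.05 - 1e-12) and np.all(p <= 0.95 + 1e-12)

    def test_monotone_in_right_side_cued_strength(self, prf_two_area, truth_two_area):
        ps = [
            nr.choice_probability(truth_two_area, prf_two_area, make_trial(0.3, 0.2, c, 0.2))
            for c in np.linspace(0.3, 0.9, 13)
        ]
        # nondecreasing throughout (the probit saturates to float-identical
        # values at large differences), strictly increasing early on
        assert np.all(np.diff(ps) >= 0)
        assert ps[3] > ps[0]

    def test_additive_offsets_cancel_but_not_under_selection(self, prf_two_area, truth_two_area):
        """alpha_task shifts both patches equally, so it drops out of the
        response difference — except through the rho-power nonlinearity."""
        shifted = {
            a: dataclasses.replace(prf, alpha_task=0.9) for a, prf in prf_two_area.items()
        }
        t = make_trial(0.35, 0.2, 0.5, 0.2)
        p0 = nr.choice_probability(truth_two_area, prf_two_area, t)
        p1 = nr.choice_probability(truth_two_area, shifted, t)
        assert p1 == pytest.approx(p0, abs=1e-12)

        sel = dataclasses.replace(truth_two_area, selection_rho=2.0)
        q0 = nr.choice_probability(sel, prf_two_area, t)
        q1 = nr.choice_probability(sel, shifted, t)
        assert abs(q1 - q0) > 1e-4

    def test_weight_response_rescaling_invariance(self, prf_two_area, truth_two_area):
        """Scaling all responses by a and all weights by 1/a leaves additive
        choice probabilities unchanged (the implied-noise degeneracy)."""
        a = 3.7
        scaled_prf = {
            k: dataclasses.replace(p, alpha_con=a * p.alpha_con, alpha_coh=a * p.alpha_coh)
            for k, p in prf_two_area.items()
        }
        scaled_model = dataclasses.replace(
            truth_two_area,
            weights={t: {k: w / a for k, w in truth_two_area.weights[t].items()} for t in TASKS},
        )
        t = make_trial(0.3, 0.1, 0.45, 0.3)
        assert nr.choice_probability(scaled_model, scaled_prf, t) == pytest.approx(
            nr.choice_probability(truth_two_area, prf_two_area, t), abs=1e-12
        )


class TestFitReadout:
    def test_parameter_counts(self, prf_eight_area, prf_two_area, truth_two_area):
        w8 = {t: {a: 0.0 for a in nr.AREAS} for t in TASKS}
        flex8 = nr.ReadoutModel(areas=nr.AREAS, weights=w8, readout_mode="flexible")
        fixed8 = nr.ReadoutModel(areas=nr.AREAS, weights=w8, readout_mode="fixed")
        assert flex8.n_free_parameters == 17
        assert fixed8.n_free_parameters == 9
        assert truth_two_area.n_free_parameters == 5

    def test_two_area_flexible_recovery(self, prf_two_area, truth_two_area):
        """Median relative parameter error below 15% across 10 seeds on
        4,000-trial sessions."""
        errs = []
        for seed in range(10):
            trials = simulate_flexible_trials(100 + seed)
            fit = nr.fit_readout(
                trials, prf_two_area, readout_mode="flexible",
                lapse=truth_two_area.lapse, n_restarts=3, seed=seed,
            )
            truth_vec = np.r_[
                [truth_two_area.weights[t][a] for t in TASKS for a in ("V1", "MT")],
                truth_two_area.beta_bias,
            ]
            fit_vec = np.r_[
                [fit.model.weights[t][a] for t in TASKS for a in ("V1", "MT")],
                fit.model.beta_bias,
            ]
            errs.extend(np.abs(fit_vec - truth_vec) / np.abs(truth_vec))
        assert np.median(errs) < 0.15

    def test_loglik_matches_recomputation(self, prf_two_area, truth_two_area, behavior_4000):
        fit = nr.fit_readout(behavior_4000, prf_two_area, readout_mode="flexible",
                             lapse=truth_two_area.lapse, n_restarts=2, seed=1)
        p = nr.choice_probabilities(fit.model, prf_two_area, behavior_4000)
        y = behavior_4000["choice"] == "right"
        from neuroreadout.linking import bernoulli_loglik
        assert fit.loglik == pytest.approx(bernoulli_loglik(p, y), abs=1e-8)

    def test_fixed_never_beats_flexible_in_sample(self, prf_two_area, truth_two_area, behavior_4000):
        flex = nr.fit_readout(behavior_4000, prf_two_area, readout_mode="flexible",
                              lapse=truth_two_area.lapse, n_restarts=3, seed=2)
        fixed = nr.fit_readout(behavior_4000, prf_two_area, readout_mode="fixed",
                               lapse=truth_two_area.lapse, n_restarts=3, seed=2)
        assert fixed.loglik <= flex.loglik + 1e-6

    def test_unset_choices_rejected(self, prf_two_area):
        cfg = nr.TaskConfig(n_runs=2, trials_per_run=10)
        trials, _ = nr.generate_task_schedule(cfg, seed=1)
        with pytest.raises(ValueError):
            nr.fit_readout(trials, prf_two_area)


class TestImpliedNoise:
    def test_reciprocal_weights(self, truth_two_area):
        model = dataclasses.replace(
            truth_two_area,
            weights={"contrast": {"V1": 1.0, "MT": 0.5}, "coherence": {"V1": 0.0, "MT": 2.0}},
        )
        noise = nr.implied_noise(model)
        assert noise["contrast"]["V1"] == 1.0
        assert noise["contrast"]["MT"] == 2.0
        assert noise["coherence"]["V1"] == np.inf
        assert noise["coherence"]["MT"] == 0.5


class TestPredictJnd:
    def test_linear_channel_closed_form(self):
        prf = linear_coherence_prf(slope=2.0)
        model = single_area_model(1.0)
        # weighted readout slope ~2 per unit coherence => JND ~0.5
        jnd = nr.predict_jnd(model, prf, "coherence", Stimulus(0.25, 0.0))
        # slight curvature of the near-linear channel shifts the root by <1%
        assert jnd == pytest.approx(0.5, rel=1e-2)

    def test_matches_grid_search(self, prf_two_area, truth_two_area):
        for base in (Stimulus(0.325, 0.15), Stimulus(0.55, 0.45)):
            for task in TASKS:
                jnd = nr.predict_jnd(truth_two_area, prf_two_area, task, base)
                # brute-force grid oracle at step 1e-5
                level = base.contrast if task == "contrast" else base.coherence
                grid = np.arange(1e-5, 1.0 - level, 1e-5)
                w = truth_two_area.weight_vector(task)
                areas = truth_two_area.areas
                if task == "contrast":
                    r0 = sum(wi * prf_two_area[a].response(base.contrast, base.coherence)
                             for wi, a in zip(w, areas))
                    rg = sum(wi * prf_two_area[a].response(base.contrast + grid, base.coherence)
                             for wi, a in zip(w, areas))
                else:
                    r0 = sum(wi * prf_two_area[a].response(base.contrast, base.coherence)
                             for wi, a in zip(w, areas))
                    rg = sum(wi * prf_two_area[a].response(base.contrast, base.coherence + grid)
                             for wi, a in zip(w, areas))
                oracle = grid[np.searchsorted(rg - r0, 1.0)]
                assert jnd == pytest.approx(oracle, abs=1e-4)

    def test_threshold_increment_simulates_to_76_percent(self, prf_two_area, truth_two_area):
        """Bernoulli simulation of 2AFC trials at base+JND vs base yields
        ~76% correct when the JND is defined at the d'=1 criterion."""
        model = dataclasses.replace(truth_two_area, beta_bias=0.0, lapse=0.0)
        base = Stimulus(0.325, 0.15)
        jnd = nr.simulated_jnd(model, prf_two_area, "contrast", base)
        rng = np.random.default_rng(41)
        n = 40_000
        correct = 0
        for side in ("left", "right"):
            if side == "right":
                t = make_trial(base.contrast, base.coherence, base.contrast + jnd, base.coherence)
            else:
                t = make_trial(base.contrast + jnd, base.coherence, base.contrast, base.coherence)
            p_right = nr.choice_probability(model, prf_two_area, t)
            chose_right = rng.random(n // 2) < p_right
            correct += np.sum(chose_right == (side == "right"))
        assert abs(correct / n - nr.PCORRECT_DPRIME1) < 0.02

    def test_non_monotone_readout_raises(self):
        prf = linear_coherence_prf(slope=2.0)
        model = single_area_model(-1.0)
        with pytest.raises(ValueError):
            nr.predict_jnd(model, prf, "coherence", Stimulus(0.25, 0.0))

    def test_insensitive_readout_not_measurable(self):
        prf = linear_coherence_prf(slope=0.001)
        model = single_area_model(1.0)
        assert np.isnan(nr.predict_jnd(model, prf, "coherence", Stimulus(0.25, 0.0)))


class TestCatchJnd:
    def test_memory_cost_one_is_plain_jnd(self, prf_two_area, truth_two_area):
        base = Stimulus(0.325, 0.15)
        plain = nr.predict_jnd(truth_two_area, prf_two_area, "contrast", base)
        catch = nr.predict_catch_jnd(truth_two_area, prf_two_area, "contrast", base,
                                     memory_cost=1.0, wrong_readout=False)
        assert catch == pytest.approx(plain, abs=1e-9)

    def test_memory_cost_doubles_linear_jnd(self):
        prf = linear_coherence_prf(slope=2.0)
        model = single_area_model(1.0)
        j1 = nr.predict_catch_jnd(model, prf, "coherence", Stimulus(0.25, 0.0),
                                  memory_cost=1.0, wrong_readout=False)
        j2 = nr.predict_catch_jnd(model, prf, "coherence", Stimulus(0.25, 0.0),
                                  memory_cost=2.0, wrong_readout=False)
        assert j2 == pytest.approx(2 * j1, rel=2e-2)

    def test_wrong_readout_insensitive_to_feature_not_measurable(self, prf_two_area):
        """A contrast-task readout with no weight on coherence-sensitive
        signal predicts catch coherence judgments are impossible."""
        model = nr.ReadoutModel(
            areas=("V1", "MT"),
            weights={"contrast": {"V1": 10.0, "MT": 0.0}, "coherence": {"V1": 0.0, "MT": 20.0}},
        )
        con_only = {
            "V1": dataclasses.replace(prf_two_area["V1"], alpha_coh=1e-9),
            "MT": prf_two_area["MT"],
        }
        jnd = nr.predict_catch_jnd(model, con_only, "coherence", Stimulus(0.325, 0.15))
        assert np.isnan(jnd)

    def test_wrong_readout_inflates_jnd(self, prf_two_area):
        model = nr.ReadoutModel(
            areas=("V1", "MT"),
            weights={"contrast": {"V1": 13.0, "MT": 1.0}, "coherence": {"V1": 1.0, "MT": 21.0}},
        )
        base = Stimulus(0.325, 0.15)
        right = nr.predict_jnd(model, prf_two_area, "coherence", base)
        wrong = nr.predict_catch_jnd(model, prf_two_area, "coherence", base)
        assert np.isnan(wrong) or wrong > 2 * right


class TestPoissonVariant:
    def test_jnds_grow_with_base_under_poisson_noise(self, prf_two_area, truth_two_area):
        """With response-dependent noise on saturating response functions the
        psychometric curve flattens at high base strengths: simulated JNDs at
        the highest base exceed those at the lowest, and exceed the additive
        model's at matched parameters."""
        poisson = dataclasses.replace(truth_two_area, noise_mode="poisson", beta_bias=0.0, lapse=0.0)
        additive = dataclasses.replace(truth_two_area, noise_mode="additive", beta_bias=0.0, lapse=0.0)
        lo, hi = Stimulus(0.325, 0.15), Stimulus(0.85, 0.6)
        j_lo = nr.simulated_jnd(poisson, prf_two_area, "contrast", lo)
        j_hi = nr.simulated_jnd(poisson, prf_two_area, "contrast", hi)
        assert np.isnan(j_hi) or j_hi > j_lo
        # and the Weber-like growth is steeper than the additive model's
        a_lo = nr.simulated_jnd(additive, prf_two_area, "contrast", lo)
        a_hi = nr.simulated_jnd(additive, prf_two_area, "contrast", hi)
        if np.isfinite(j_hi) and np.isfinite(a_hi):
            assert j_hi / j_lo > a_hi / a_lo
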