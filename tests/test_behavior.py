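"""Generative behavior model: mixture probabilities, simulation, recovery."""

import numpy as np
import pytest

from tachometry import (
    BehaviorModelParams,
    DesignSpec,
    apply_exclusions,
    fit_behavior_model,
    generate_design,
    pool_accuracy_1ms,
    response_probability,
    simulate_experiment,
)


class TestResponseProbability:
    def test_pure_guessing(self):
        p = BehaviorModelParams(A_s=0.0, A_g=0.0)
        for cong in ("congruent", "incongruent"):
            probs = response_probability(np.arange(-200, 1001, 50), cong, p)
            assert np.allclose(probs, 0.5)

    def test_capture_peak_arithmetic(self):
        # at the capture center with w_g ~ 0: 0.1*0.5 + 0.8*[cong]
        p = BehaviorModelParams(A_s=0.8, mu_s=250, A_g=0.0)
        assert response_probability(250, "congruent", p) == pytest.approx(0.9)
        assert response_probability(250, "incongruent", p) == pytest.approx(0.1)

    def test_goal_asymptote(self):
        p = BehaviorModelParams(A_s=0.8, A_g=1.0, a_goal=0.97)
        for cong in ("congruent", "incongruent"):
            assert response_probability(5000, cong, p) == pytest.approx(0.97, abs=1e-6)

    def test_convex_combination_bounds_and_ordering(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = BehaviorModelParams(
                A_s=rng.uniform(0, 1), mu_s=rng.uniform(0, 500),
                sigma_s=rng.uniform(10, 150), A_g=rng.uniform(0, 1),
                mu_g=rng.uniform(100, 700), tau_g=rng.uniform(5, 120),
                a_goal=rng.uniform(0.5, 1),
            )
            t = np.arange(-200, 1001)
            pc = response_probability(t, "congruent", p)
            pi = response_probability(t, "incongruent", p)
            assert np.all((pc >= 0) & (pc <= 1) & (pi >= 0) & (pi <= 1))
            assert np.all(pc >= pi - 1e-12)

    def test_joint_weight_constraint_by_clipping(self):
        # capture and goal windows overlap heavily: weights must still sum <= 1
        from tachometry.behavior import capture_weight, goal_weight

        p = BehaviorModelParams(A_s=1.0, mu_s=400, sigma_s=200,
                                A_g=1.0, mu_g=300, tau_g=30)
        t = np.arange(-200, 1001)
        assert np.all(capture_weight(t, p) + goal_weight(t, p) <= 1 + 1e-12)


@pytest.fixture(scope="module")
def design():
    return generate_design(
        DesignSpec(task="spatial_stroop", n_participants=1, seed=21)
    )


class TestSimulateExperiment:
    def test_same_seed_identical(self, design, default_params):
        a = simulate_experiment(design, default_params, seed=1).data
        b = simulate_experiment(design, default_params, seed=1).data
        assert a.equals(b)

    def test_refuses_filled_design(self, design, default_params):
        filled = simulate_experiment(design, default_params, seed=1)
        with pytest.raises(ValueError, match="overwrite"):
            simulate_experiment(filled, default_params, seed=2)

    def test_rt_respects_bounds_and_deadline_flag(self, design, default_params):
        t = simulate_experiment(design, default_params, seed=3).data
        rt = t["rt_ms"].astype(int)
        lo, hi = default_params.rt_bounds
        assert rt.between(lo, hi).all()
        assert (t["on_time"] == (rt <= 1000)).all()

    def test_null_model_accuracy_difference_within_binomial_band(self, design):
        # A_s = 0: both conditions are the same Bernoulli process; the
        # accuracy difference must stay inside the 99% null band at n=5940
        null = BehaviorModelParams(A_s=0.0)
        t = simulate_experiment(design, null, seed=17)
        df = t.data[~t.data.is_practice]
        acc = df.groupby("congruency")["correct"].mean()
        diff = acc["congruent"] - acc["incongruent"]
        p_bar = df["correct"].mean()
        se = np.sqrt(p_bar * (1 - p_bar) * (1 / 2970 + 1 / 2970))
        assert abs(diff) < 2.576 * se

    def test_incongruent_dip_below_chance_in_raw_bins(self, design, default_params):
        # Monte-Carlo check of the generative model: raw 1-ms accuracy near
        # the capture center falls below 0.5 for incongruent trials
        t = simulate_experiment(design, default_params, seed=29)
        analyzed, _ = apply_exclusions(t)
        inc = analyzed.data[analyzed.data.congruency == "incongruent"]
        window = inc[(inc.rpt_ms >= 230) & (inc.rpt_ms <= 270)]
        assert len(window) > 50
        assert window["correct"].mean() < 0.5


class TestFitBehaviorModel:
    def test_minimum_trial_precondition(self):
        from conftest import make_trials

        t = make_trials(np.arange(100), np.ones(100, bool))
        with pytest.raises(ValueError, match="at least"):
            fit_behavior_model(t)

    def test_recovery_at_moderate_scale(self, default_params):
        spec = DesignSpec(task="spatial_stroop", n_participants=1, seed=31)
        t = simulate_experiment(generate_design(spec), default_params, seed=32)
        analyzed, _ = apply_exclusions(t)
        fit = fit_behavior_model(analyzed, seed=0)
        assert fit.converged
        assert fit.params.mu_s == pytest.approx(default_params.mu_s, abs=25)
        assert fit.params.A_s == pytest.approx(default_params.A_s, abs=0.1)

    def test_null_recovery_a_s_near_zero(self):
        null = BehaviorModelParams(A_s=0.0)
        spec = DesignSpec(task="simon", n_participants=1, n_sessions=2, seed=33)
        t = simulate_experiment(generate_design(spec), null, seed=34)
        analyzed, _ = apply_exclusions(t)
        fit = fit_behavior_model(analyzed, seed=0)
        assert fit.params.A_s <= 0.05

    def test_deterministic_given_seed(self, small_experiment):
        analyzed, _ = small_experiment
        a = fit_behavior_model(analyzed, seed=5)
        b = fit_behavior_model(analyzed, seed=5)
        assert a.params == b.params
        assert a.log_likelihood == b.log_likelihood

    def test_recovery_rmse_improves_with_n(self, default_params):
        # mu_s RMSE over 20 replicate seeds shrinks from ~3k to ~30k trials
        sizes = {"small": (1, 3), "large": (5, 5)}  # (participants, sessions)
        errs = {name: [] for name in sizes}
        for rep in range(20):
            for name, (npart, sessions) in sizes.items():
                spec = DesignSpec(task="spatial_stroop", n_participants=npart,
                                  n_sessions=sessions, seed=100 + rep)
                t = simulate_experiment(generate_design(spec), default_params,
                                        seed=200 + rep)
                analyzed, _ = apply_exclusions(t)
                fit = fit_behavior_model(analyzed, seed=0, n_starts=3)
                errs[name].append(fit.params.mu_s - default_params.mu_s)
        rmse = {k: float(np.sqrt(np.mean(np.square(v)))) for k, v in errs.items()}
        assert rmse["large"] < rmse["small"]
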