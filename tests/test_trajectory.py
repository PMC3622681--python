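"""FC-PPF recursions, the duration mixture, and their independent oracles."""

from dataclasses import replace

import numpy as np
import pytest

from ofcbmi import (
    DurationGrid,
    GaussianBelief,
    KinematicTuningModel,
    duration_predictive_loglik,
    fc_p_ppf_decode,
    fc_ppf_decode,
    ppf_predict,
    ppf_update,
    rw_ppf,
    solve_lqg,
)
from ofcbmi.ofc import LTISystem, goal_state
from ofcbmi.trajectory import FCPPFBank, ppf_update_gaussian
from ofcbmi.task import target_positions


def _belief(mean=None, cov=None):
    mean = np.zeros(6) if mean is None else np.asarray(mean, float)
    cov = 1e-10 * np.eye(6) if cov is None else np.asarray(cov, float)
    return GaussianBelief(mean=mean, cov=cov)


def _toy_1d_model(alpha, beta_x):
    return KinematicTuningModel(alpha=np.array([alpha]),
                                beta=np.array([[beta_x, 0.0, 0.0, 0.0]]))


class TestPredict:
    def test_no_observation_prediction_is_straight_to_target(
            self, plant, cost_template):
        target = np.array([0.0, 0.1])
        cost = replace(cost_template, target=target, T=120)
        gains = solve_lqg(plant, cost)
        belief = _belief()
        path = []
        for t in range(1, 121):
            belief = ppf_predict(belief, plant, gains.gain(t), gains.x_star)
            path.append(belief.mean[:2])
        path = np.asarray(path)
        assert np.abs(path[:, 0]).max() < 0.02 * 0.1  # lateral deviation
        assert np.linalg.norm(path[-1] - target) < 0.01

    def test_goal_with_zero_noise_is_fixed_point(self, plant, cost_template):
        sys0 = LTISystem(A=plant.A, B=plant.B, W=np.zeros((6, 6)))
        cost = replace(cost_template, target=np.array([0.05, 0.05]), T=50)
        gains = solve_lqg(sys0, cost)
        belief = GaussianBelief(mean=gains.x_star, cov=np.zeros((6, 6)))
        out = ppf_predict(belief, sys0, gains.gain(1), gains.x_star)
        np.testing.assert_allclose(out.mean, gains.x_star, atol=1e-12)
        np.testing.assert_allclose(out.cov, 0, atol=1e-15)

    def test_covariance_step_matches_hand_lyapunov(self, plant):
        """Explicit matrix arithmetic oracle for one covariance step."""
        L = np.zeros((2, 6))
        L[0, 0], L[1, 1] = 3.0, 2.0
        P0 = np.diag([1e-4, 2e-4, 1e-2, 1e-2, 0.5, 0.5])
        belief = GaussianBelief(mean=np.zeros(6), cov=P0)
        out_open = ppf_predict(belief, plant, L, np.zeros(6),
                               closed_loop_cov=False)
        np.testing.assert_allclose(out_open.cov,
                                   plant.A @ P0 @ plant.A.T + plant.W,
                                   atol=1e-14)
        out_closed = ppf_predict(belief, plant, L, np.zeros(6),
                                 closed_loop_cov=True)
        M = plant.A - plant.B @ L
        np.testing.assert_allclose(out_closed.cov, M @ P0 @ M.T + plant.W,
                                   atol=1e-14)

    def test_dimension_mismatch_rejected(self, plant):
        with pytest.raises(ValueError):
            ppf_predict(_belief(), plant, np.zeros((2, 5)), np.zeros(6))


class TestUpdate:
    def test_zero_neurons_returns_prediction(self, plant):
        model = KinematicTuningModel(alpha=np.zeros(0), beta=np.zeros((0, 4)))
        pred = _belief(cov=1e-3 * np.eye(6))
        post = ppf_update(pred, np.zeros(0), model, 0.005)
        np.testing.assert_array_equal(post.mean, pred.mean)
        np.testing.assert_array_equal(post.cov, pred.cov)

    @pytest.mark.parametrize("spike", [0, 1])
    def test_matches_dense_grid_bayes_oracle(self, spike):
        """1-D position toy vs exact grid posterior, <=1e-3 relative."""
        bin_s = 0.005
        model = _toy_1d_model(np.log(5.0), 4.0)
        m0, s0 = 0.04, 0.012
        cov = np.diag([s0**2, 1e-12, 1e-12, 1e-12, 1e-12, 1e-12])
        pred = GaussianBelief(mean=np.array([m0, 0, 0, 0, 0, 0]), cov=cov)
        post = ppf_update(pred, np.array([spike]), model, bin_s)

        xs = np.linspace(m0 - 8 * s0, m0 + 8 * s0, 40001)
        lam_dt = np.exp(np.log(5.0) + 4.0 * xs) * bin_s
        lik = lam_dt if spike else (1 - lam_dt)
        prior = np.exp(-0.5 * ((xs - m0) / s0) ** 2)
        w = lik * prior
        w /= w.sum()
        mean_g = float(np.sum(w * xs))
        var_g = float(np.sum(w * (xs - mean_g) ** 2))
        assert abs(post.mean[0] - mean_g) / abs(mean_g) < 1e-3
        assert abs(post.cov[0, 0] - var_g) / var_g < 2e-3

    def test_spike_moves_estimate_along_preferred_direction(self):
        model = _toy_1d_model(np.log(5.0), 4.0)
        pred = _belief(cov=1e-4 * np.eye(6))
        post_spike = ppf_update(pred, np.array([1]), model, 0.005)
        post_quiet = ppf_update(pred, np.array([0]), model, 0.005)
        assert post_spike.mean[0] > pred.mean[0]
        assert post_quiet.mean[0] < pred.mean[0]

    def test_posterior_cov_dominated_by_prediction_cov(self, fitted_models):
        """Information is only ever added: post.cov <= pred.cov (Loewner)."""
        _, kmodel, _ = fitted_models
        rng = np.random.default_rng(8)
        pred = _belief(mean=rng.standard_normal(6) * 0.05,
                       cov=1e-3 * np.eye(6))
        for _ in range(10):
            dN = (rng.random(kmodel.n_neurons) < 0.2).astype(float)
            post = ppf_update(pred, dN, kmodel, 0.005)
            eigs = np.linalg.eigvalsh(pred.cov - post.cov)
            assert eigs.min() > -1e-12
            pred = post

    def test_wrong_neuron_count_rejected(self):
        model = _toy_1d_model(1.0, 1.0)
        with pytest.raises(ValueError):
            ppf_update(_belief(), np.zeros(3), model, 0.005)


class TestKalmanReduction:
    def test_gaussian_observation_filter_equals_kalman(self, plant,
                                                       cost_template):
        """With Gaussian observations the PPF recursions are a Kalman filter."""
        rng = np.random.default_rng(3)
        cost = replace(cost_template, target=np.array([0.1, 0]), T=40)
        gains = solve_lqg(plant, cost)
        C = np.zeros((2, 6))
        C[0, 0] = C[1, 1] = 1.0
        R_obs = 1e-4 * np.eye(2)

        belief = _belief(cov=1e-6 * np.eye(6))
        mean_k, cov_k = belief.mean.copy(), belief.cov.copy()
        for t in range(1, 41):
            y = rng.standard_normal(2) * 0.01
            pred = ppf_predict(belief, plant, gains.gain(t), gains.x_star)
            belief = ppf_update_gaussian(pred, y, C, R_obs)
            # textbook Kalman update as the oracle
            M = plant.A - plant.B @ gains.gain(t)
            mean_p = gains.x_star + M @ (mean_k - gains.x_star)
            cov_p = plant.A @ cov_k @ plant.A.T + plant.W
            S = C @ cov_p @ C.T + R_obs
            K = cov_p @ C.T @ np.linalg.inv(S)
            mean_k = mean_p + K @ (y - C @ mean_p)
            cov_k = (np.eye(6) - K @ C) @ cov_p
            np.testing.assert_allclose(belief.mean, mean_k, atol=1e-10)
            np.testing.assert_allclose(belief.cov, cov_k, atol=1e-12)


class TestPredictiveLikelihood:
    @pytest.mark.parametrize("spike", [0, 1])
    def test_matches_quadrature_oracle(self, spike):
        """Laplace approximation within 1e-2 of numerical integration."""
        bin_s = 0.005
        model = _toy_1d_model(np.log(12.0), 6.0)
        m0, s0 = 0.03, 0.015
        cov = np.diag([s0**2] + [1e-14] * 5)
        pred = GaussianBelief(mean=np.array([m0, 0, 0, 0, 0, 0]), cov=cov)
        post = ppf_update(pred, np.array([spike]), model, bin_s)
        ll = duration_predictive_loglik(pred, post, np.array([spike]),
                                        model, bin_s)
        xs = np.linspace(m0 - 10 * s0, m0 + 10 * s0, 60001)
        dx = xs[1] - xs[0]
        lam_dt = np.clip(np.exp(np.log(12.0) + 6.0 * xs) * bin_s, 0, 0.95)
        lik = lam_dt if spike else (1 - lam_dt)
        prior = np.exp(-0.5 * ((xs - m0) / s0) ** 2) / (
            s0 * np.sqrt(2 * np.pi))
        ll_quad = np.log(np.sum(lik * prior) * dx)
        assert abs(ll - ll_quad) < 1e-2

    def test_untuned_ensemble_keeps_weights_uniform(self, plant,
                                                    cost_template, config):
        model = KinematicTuningModel(alpha=np.full(5, np.log(5.0)),
                                     beta=np.zeros((5, 4)))
        grid = DurationGrid((60, 90, 120))
        rng = np.random.default_rng(0)
        spikes = (rng.random((5, 60)) < 0.025).astype(np.uint8)
        tpos = target_positions(config)
        _, w = fc_p_ppf_decode(spikes, tpos[0], grid, plant, cost_template,
                               model)
        np.testing.assert_allclose(w[:60], 1 / 3, atol=1e-9)

    def test_log_weight_translation_invariance(self):
        """Adding a constant to all per-bin log-liks leaves weights fixed."""
        from scipy.special import logsumexp

        lw = np.array([-1200.0, -1201.5, -1199.2])
        w1 = np.exp(lw - logsumexp(lw))
        lw2 = lw + 500.0
        w2 = np.exp(lw2 - logsumexp(lw2))
        np.testing.assert_allclose(w1, w2)


class TestMixture:
    def test_singleton_grid_equals_single_filter(self, plant, cost_template,
                                                 fitted_models, config,
                                                 manual_session):
        _, kmodel, _ = fitted_models
        records, _ = manual_session
        rec = records[0]
        tpos = target_positions(config)[rec.cued_target]
        sp = rec.movement_spikes()[:, :100]
        traj_a, w = fc_p_ppf_decode(sp, tpos, DurationGrid((120,)), plant,
                                    cost_template, kmodel)
        traj_b = fc_ppf_decode(sp, tpos, 120, plant, cost_template, kmodel)
        np.testing.assert_allclose(traj_a, traj_b)
        np.testing.assert_allclose(w, 1.0)

    def test_weights_normalized_every_bin(self, plant, cost_template,
                                          fitted_models, config,
                                          manual_session):
        _, kmodel, _ = fitted_models
        records, _ = manual_session
        rec = records[1]
        tpos = target_positions(config)[rec.cued_target]
        grid = DurationGrid.from_seconds(bin_s=config.bin_s)
        _, w = fc_p_ppf_decode(rec.movement_spikes(), tpos, grid, plant,
                               cost_template, kmodel)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_elapsed_durations_drop_out(self, plant, cost_template,
                                        fitted_models, config):
        _, kmodel, _ = fitted_models
        grid = DurationGrid((20, 40, 60))
        rng = np.random.default_rng(1)
        spikes = (rng.random((kmodel.n_neurons, 55)) < 0.02).astype(np.uint8)
        tpos = target_positions(config)[0]
        _, w = fc_p_ppf_decode(spikes, tpos, grid, plant, cost_template,
                               kmodel)
        assert np.all(w[25:, 0] == 0)  # T=20 retired after bin 20
        assert np.all(w[45:, 1] == 0)
        np.testing.assert_allclose(w[45:, 2], 1.0)

    def test_untuned_cells_degrade_to_prior_path(self, plant, cost_template,
                                                 config):
        """With beta = 0 the mixture output is the prior prediction path."""
        model = KinematicTuningModel(alpha=np.full(3, np.log(5.0)),
                                     beta=np.zeros((3, 4)))
        grid = DurationGrid((120,))
        rng = np.random.default_rng(2)
        spikes = (rng.random((3, 120)) < 0.025).astype(np.uint8)
        target = target_positions(config)[2]
        traj, _ = fc_p_ppf_decode(spikes, target, grid, plant, cost_template,
                                  model)
        # oracle: pure prediction recursion
        gains = solve_lqg(plant, replace(cost_template, target=target, T=120))
        belief = _belief()
        for t in range(1, 121):
            belief = ppf_predict(belief, plant, gains.gain(t), gains.x_star)
            np.testing.assert_allclose(traj[t - 1], belief.mean, atol=1e-9)


class TestRWPPF:
    def test_equivalent_to_zero_gain_zero_B_filter(self, plant,
                                                   fitted_models):
        _, kmodel, _ = fitted_models
        rng = np.random.default_rng(9)
        spikes = (rng.random((kmodel.n_neurons, 80)) < 0.03).astype(np.uint8)
        traj = rw_ppf(spikes, kmodel, plant)
        # oracle: explicitly zero out B and run the FC recursions
        sys_b0 = LTISystem(A=plant.A, B=np.zeros((6, 2)), W=plant.W)
        belief = _belief()
        gains_dummy = np.ones((2, 6))  # irrelevant once B = 0
        for t in range(80):
            pred = ppf_predict(belief, sys_b0, gains_dummy, np.zeros(6))
            belief = ppf_update(pred, spikes[:, t], kmodel, 0.005)
            np.testing.assert_array_equal(traj[t], belief.mean)

    def test_stays_near_init_without_spikes_or_noise(self, fitted_models,
                                                     plant):
        _, kmodel, _ = fitted_models
        sys0 = LTISystem(A=plant.A, B=plant.B, W=1e-18 * np.eye(6))
        # silence is still an observation: hold the state near the origin,
        # where predicted rates match the observed absence of spikes
        spikes = np.zeros((kmodel.n_neurons, 100), dtype=np.uint8)
        traj = rw_ppf(spikes, kmodel, sys0)
        assert np.linalg.norm(traj[-1, :2]) < 0.02

    def test_less_accurate_than_target_aware_filter(
            self, plant, cost_template, fitted_models, config,
            manual_session):
        """Paired over trials: knowing the target reduces RMS error."""
        from ofcbmi import rms_error

        _, kmodel, _ = fitted_models
        records, _ = manual_session
        tpos = target_positions(config)
        wins = 0
        trials = records[:30]
        for rec in trials:
            sp = rec.movement_spikes()
            kin = rec.movement_kinematics()[:, :2]
            fc = fc_ppf_decode(sp, tpos[rec.cued_target],
                               rec.intended_duration_bins, plant,
                               cost_template, kmodel)
            rw = rw_ppf(sp, kmodel, plant)
            wins += (rms_error(rw[:, :2], kin)
                     > rms_error(fc[:, :2], kin))
        assert wins > len(trials) / 2
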