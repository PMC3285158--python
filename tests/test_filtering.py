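"""Sigma-point filter: linear-Gaussian equivalence, update/predict contracts,
self-consistency and V0-misspecification behaviour."""

import numpy as np
import pytest

from balloonassim import (DEFAULT_PARAMS, FilterConfig, compare_v0_scenarios,
                          run_assimilation, simulate_bold, state_excursions)
from balloonassim.filtering import (FilterDivergenceError, encode_params,
                                    decode_params, sigma_points, ukf_predict,
                                    ukf_update, _run_filter)
from balloonassim.synthetic import (default_single_region_scenario,
                                    make_single_region_dataset,
                                    offset_prior_params)


def closed_form_kalman(F, H, Q, R, x0, P0, ys):
    """Textbook linear Kalman filter, the independent oracle."""
    x, P = x0.copy(), P0.copy()
    xs, Ps = [], []
    for i, y in enumerate(ys):
        if i > 0:
            x = F @ x
            P = F @ P @ F.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (y - H @ x)
        P = P - K @ S @ K.T
        xs.append(x.copy())
        Ps.append(P.copy())
    return np.array(xs), np.array(Ps)


class TestLinearGaussianEquivalence:
    def test_matches_closed_form_kalman(self):
        """On a frozen linear system the sigma-point filter must reproduce
        the closed-form Kalman filter to near machine precision."""
        rng = np.random.default_rng(42)
        F = np.array([[0.9, 0.1], [0.0, 0.95]])
        H = np.array([[1.0, 0.5]])
        Q = 0.01 * np.eye(2)
        R = np.array([[0.04]])
        x0 = np.array([0.3, -0.2])
        P0 = np.diag([0.5, 0.25])
        n = 40
        ys = rng.normal(0.0, 0.5, size=(n, 1))

        cfg = FilterConfig(measurement_var=0.04, alpha_ukf=1.0)
        res = _run_filter(x0, P0, lambda X, i: X @ F.T, lambda X: X @ H.T,
                          Q, R, ys, cfg)
        xs_kf, Ps_kf = closed_form_kalman(F, H, Q, R, x0, P0, ys)
        assert np.max(np.abs(res["filtered_means"] - xs_kf)) <= 1e-10
        assert np.max(np.abs(res["filtered_covs"] - Ps_kf)) <= 1e-10


class TestUpdateContracts:
    def _prior(self):
        x = np.array([0.1, -0.3, 0.2])
        P = np.diag([0.2, 0.1, 0.3])
        return x, P

    def test_zero_innovation_leaves_mean_unchanged(self):
        x, P = self._prior()
        cfg = FilterConfig(measurement_var=0.01)
        hx = lambda X: X @ np.array([1.0, 0.0, 2.0])
        y = float(hx(x[None, :])[0])
        x_post, _, innov, _ = ukf_update(x, P, y, hx, np.array([[0.01]]), cfg)
        assert innov == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(x_post, x, atol=1e-12)

    def test_infinite_noise_limit_keeps_prior(self):
        x, P = self._prior()
        cfg = FilterConfig(measurement_var=1.0)
        hx = lambda X: X @ np.array([1.0, 0.0, 2.0])
        x_post, P_post, _, _ = ukf_update(x, P, 5.0, hx,
                                          np.array([[1e12]]), cfg)
        np.testing.assert_allclose(x_post, x, atol=1e-9)
        np.testing.assert_allclose(P_post, P, atol=1e-9)

    def test_posterior_covariance_symmetric_psd(self):
        x, P = self._prior()
        cfg = FilterConfig(measurement_var=0.01)
        hx = lambda X: np.column_stack([X[:, 0] ** 2, X[:, 2]])
        _, P_post, _, _ = ukf_update(x, P, np.array([0.5, 0.1]), hx,
                                     0.01 * np.eye(2), cfg)
        np.testing.assert_allclose(P_post, P_post.T, atol=1e-14)
        assert np.linalg.eigvalsh(P_post).min() > -1e-12


class TestPredictContracts:
    def test_resting_mean_stays_at_rest_without_noise(self, block_stimulus):
        """Propagating the resting augmented distribution with zero process
        noise and no input leaves the mean at rest."""
        cfg = FilterConfig(measurement_var=1e-4)
        times = np.array([0.0, 2.0])
        bold = np.zeros(2)
        res = run_assimilation(times, bold, block_stimulus.__class__(
            onsets=(), durations=(), sampling_dt=2.0), 0.1, cfg)
        np.testing.assert_allclose(res.state_means[-1],
                                   [0.0, 1.0, 1.0, 1.0], atol=1e-6)

    def test_parameter_block_identity_dynamics(self):
        """With zero random-walk noise the parameter mean is unchanged by
        prediction (identity dynamics)."""
        cfg = FilterConfig(measurement_var=1e-4)
        x = np.array([0.0, 1.0, 1.0, 1.0, np.log(0.5)])
        P = np.diag([1e-6] * 4 + [0.25])
        Q = np.zeros((5, 5))

        def fx(X):
            return X  # states frozen; only checking the parameter column

        x_pred, _, _ = ukf_predict(x, P, fx, Q, cfg)
        assert x_pred[4] == pytest.approx(np.log(0.5), abs=1e-12)

    def test_covariance_matches_jacobian_linearization(self, block_stimulus):
        """In the near-linear small-perturbation regime the unscented
        covariance propagation agrees with an explicit finite-difference
        Jacobian linearization within 5 % (Frobenius)."""
        from balloonassim import _kernels

        cfg = FilterConfig(measurement_var=1e-4, alpha_ukf=1.0)
        p = DEFAULT_PARAMS
        x = np.array([0.05, 1.1, 1.05, 0.95])
        P = 1e-6 * np.eye(4)
        dt, nsub = 0.1, 5
        u_seq = np.zeros(nsub)

        def advance(rows):
            rows = np.ascontiguousarray(rows)
            m = rows.shape[0]
            ones = np.ones(m)
            _kernels.propagate_balloon_batch(
                rows, p.epsilon * ones, p.tau_s * ones, p.tau_f * ones,
                p.tau_0 * ones, p.E0 * ones, 1.0 / p.alpha, u_seq, dt)
            return rows

        _, P_ut, _ = ukf_predict(x, P, advance, np.zeros((4, 4)), cfg)

        # finite-difference Jacobian oracle
        eps = 1e-7
        J = np.empty((4, 4))
        base = advance(x[None, :].copy())[0]
        for j in range(4):
            xp = x.copy()
            xp[j] += eps
            J[:, j] = (advance(xp[None, :].copy())[0] - base) / eps
        P_lin = J @ P @ J.T
        rel = np.linalg.norm(P_ut - P_lin) / np.linalg.norm(P_lin)
        assert rel < 0.05


class TestRunAssimilation:
    def test_noiseless_self_consistency(self, block_stimulus, sample_times):
        """A noiseless series generated at the filter's own prior means is
        reconstructed essentially exactly, with negligible parameter drift."""
        p = DEFAULT_PARAMS.with_v0(0.1)
        sim = simulate_bold(p, block_stimulus, sample_times, noise_sd=0.0)
        cfg = FilterConfig(measurement_var=1e-8)
        res = run_assimilation(sample_times, sim.bold_noiseless,
                               block_stimulus, 0.1, cfg)
        assert res.bold_rmse() < 1e-3
        assert abs(res.params_estimate.epsilon - p.epsilon) / p.epsilon < 0.05

    def test_innovation_whiteness_on_well_specified_run(self):
        rhos = []
        for seed in range(5):
            sc = default_single_region_scenario(seed=seed)
            ds = make_single_region_dataset(sc)
            cfg = FilterConfig(measurement_var=ds.noise_sd ** 2)
            res = run_assimilation(ds.times, ds.bold_noisy, sc.stimulus(),
                                   0.1, cfg)
            inn = res.innovations[1:]
            rhos.append(np.corrcoef(inn[:-1], inn[1:])[0, 1])
        assert abs(float(np.median(rhos))) < 0.2

    def test_filtered_covariances_symmetric_psd(self):
        sc = default_single_region_scenario(seed=0)
        ds = make_single_region_dataset(sc)
        cfg = FilterConfig(measurement_var=ds.noise_sd ** 2)
        res = run_assimilation(ds.times, ds.bold_noisy, sc.stimulus(), 0.1, cfg)
        for P in res.filtered_covs[::40]:
            np.testing.assert_allclose(P, P.T, atol=1e-12)
            assert np.linalg.eigvalsh(P).min() > -1e-10

    def test_nonuniform_timestamps_rejected(self, block_stimulus):
        with pytest.raises(ValueError):
            run_assimilation([0.0, 2.0, 5.0], [0.0, 0.0, 0.0],
                             block_stimulus, 0.1)

    def test_nan_observation_skipped_not_fatal(self, block_stimulus,
                                               sample_times):
        sim = simulate_bold(DEFAULT_PARAMS.with_v0(0.1), block_stimulus,
                            sample_times, noise_sd=0.002, seed=0)
        y = sim.bold_noisy.copy()
        y[50] = np.nan
        cfg = FilterConfig(measurement_var=4e-6)
        res = run_assimilation(sample_times, y, block_stimulus, 0.1, cfg)
        assert res.skipped_updates == 1
        assert np.isfinite(res.params_estimate.epsilon)

    def test_smoothing_pass_runs_and_matches_terminal_state(self,
                                                            block_stimulus,
                                                            sample_times):
        sim = simulate_bold(DEFAULT_PARAMS.with_v0(0.1), block_stimulus,
                            sample_times, noise_sd=0.002, seed=1)
        cfg = FilterConfig(measurement_var=4e-6, smooth=True)
        res = run_assimilation(sample_times, sim.bold_noisy, block_stimulus,
                               0.1, cfg)
        assert res.smoothed_means is not None
        np.testing.assert_allclose(res.smoothed_means[-1],
                                   res.filtered_means[-1], atol=1e-12)


class TestV0Misspecification:
    def test_underestimated_v0_inflates_epsilon(self):
        """Assimilating truth-V0=0.1 data with an assumed V0=0.02 must fit
        the BOLD signal comparably while overestimating neuronal efficacy
        and enlarging the reconstructed state excursions."""
        sc = default_single_region_scenario(seed=3)
        ds = make_single_region_dataset(sc)
        cfg = FilterConfig(measurement_var=ds.noise_sd ** 2)
        cmp = compare_v0_scenarios(ds.times, ds.bold_noisy, sc.stimulus(),
                                   0.1, 0.02, cfg)
        r = cmp.report
        assert r["epsilon"]["assumed"] > sc.params.epsilon
        assert r["bold_rmse_ratio"] < 1.5
        for k in ("f", "v", "q"):
            assert r["excursion_ratios"][k] > 1.0

    def test_identical_v0_gives_identical_results(self):
        sc = default_single_region_scenario(seed=2)
        ds = make_single_region_dataset(sc)
        cfg = FilterConfig(measurement_var=ds.noise_sd ** 2)
        cmp = compare_v0_scenarios(ds.times, ds.bold_noisy, sc.stimulus(),
                                   0.1, 0.1, cfg)
        np.testing.assert_array_equal(cmp.result_actual.filtered_means,
                                      cmp.result_assumed.filtered_means)


class TestParamCodec:
    def test_encode_decode_round_trip(self):
        p = DEFAULT_PARAMS
        vec = encode_params(p)
        back = decode_params(vec, p)
        for name in ("epsilon", "tau_s", "tau_f", "tau_0", "E0"):
            assert getattr(back, name) == pytest.approx(getattr(p, name),
                                                        rel=1e-12)

    def test_sigma_points_reproduce_moments(self):
        cfg = FilterConfig(measurement_var=1.0, alpha_ukf=1.0)
        x = np.array([1.0, -2.0])
        P = np.array([[0.5, 0.1], [0.1, 0.3]])
        X, Wm, Wc = sigma_points(x, P, cfg)
        np.testing.assert_allclose(Wm @ X, x, atol=1e-12)
        dev = X - x
        np.testing.assert_allclose((dev.T * Wc) @ dev, P, atol=1e-12)
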