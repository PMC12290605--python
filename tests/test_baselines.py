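"""Static FC, sliding-window (+ CV window length), and DCC-GARCH baselines."""

import math

import numpy as np
import pytest

from tvfc import baselines, simkit
from tvfc.datatypes import TimeSeriesData


class TestStaticFC:
    def test_identical_columns_full_correlation(self, rng):
        col = rng.standard_normal(100)
        _, corr = baselines.static_fc(np.column_stack([col, col]))
        assert np.isclose(corr[0, 1], 1.0)

    def test_orthogonal_columns_zero_correlation(self):
        y = np.array([[1, 1], [-1, 1], [1, -1], [-1, -1]], dtype=float)
        _, corr = baselines.static_fc(y)
        assert np.isclose(corr[0, 1], 0.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            baselines.static_fc(np.column_stack([np.ones(10), np.arange(10.0)]))

    def test_mean_over_noiseless_trials_near_generating_constant(self):
        rs = []
        for seed in range(1, 51):
            data, _ = simkit.simulate_dataset("constant", n=400, seed=seed)
            _, corr = baselines.static_fc(data)
            rs.append(corr[0, 1])
        assert abs(np.mean(rs) - 0.8) < 0.01


class TestHighpassFilter:
    def test_dc_removed(self):
        y = np.full((200, 1), 3.0)
        out = baselines.highpass_filter(y, cutoff_hz=0.02, tr=2.0)
        assert np.max(np.abs(out)) < 1e-6 * 3.0 + 1e-9

    def test_passband_amplitude_preserved(self):
        tr = 2.0
        t = np.arange(1000) * tr
        y = np.sin(2 * np.pi * 0.1 * t)[:, None]  # 0.1 Hz, well above 0.01 Hz cutoff
        out = baselines.highpass_filter(y, cutoff_hz=0.01, tr=tr)
        assert abs(out[200:-200].std() - y[200:-200].std()) / y.std() < 0.05

    def test_stopband_attenuated(self):
        tr = 2.0
        t = np.arange(4000) * tr
        y = np.sin(2 * np.pi * 0.004 * t)[:, None]  # 0.2x the 0.02 Hz cutoff
        out = baselines.highpass_filter(y, cutoff_hz=0.02, tr=tr)
        assert out.std() < 0.1 * y.std()

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            baselines.highpass_filter(np.zeros((100, 1)), cutoff_hz=0.3, tr=2.0)


class TestSlidingWindow:
    def test_output_length_matches_input(self):
        data, _ = simkit.simulate_dataset("periodic_slow", n=200, seed=0)
        for omega in (20.0, 61.0, 180.0):
            traj = baselines.sw_tvfc(data, omega)
            assert traj.n == data.n

    def test_full_window_equals_static(self):
        data, _ = simkit.simulate_dataset("constant", n=100, seed=1)
        w_seconds = data.n * data.tr
        traj = baselines.sw_tvfc(data, w_seconds, filter_highpass=False)
        _, corr = baselines.static_fc(data)
        # interior estimates (full overlap with the data) match static FC
        mid = traj.sigmas[data.n // 2]
        # zero-mean convention vs demeaned static: z-scored data -> close
        assert abs(mid[0, 1] - corr[0, 1]) < 0.02

    def test_identical_columns_unit_correlation(self, rng):
        col = rng.standard_normal(120)
        data = TimeSeriesData(y=np.column_stack([col, col]), tr=2.0)
        traj = baselines.sw_tvfc(data, 30.0, filter_highpass=False)
        np.testing.assert_allclose(traj.edge(0, 1), 1.0, atol=1e-10)

    def test_valid_correlation_trajectory(self):
        data, _ = simkit.simulate_dataset("stepwise", n=300, seed=2)
        traj = baselines.sw_tvfc(data, 40.0)
        diag = np.diagonal(traj.sigmas, axis1=1, axis2=2)
        np.testing.assert_allclose(diag, 1.0)
        assert np.all(np.abs(traj.sigmas) <= 1.0 + 1e-12)

    def test_too_short_window_rejected(self):
        data, _ = simkit.simulate_dataset("null", n=100, seed=0)
        with pytest.raises(ValueError):
            baselines.sw_tvfc(data, 2.0)  # 1 volume at TR=2


class TestCvWindowLength:
    def test_single_candidate_returned(self):
        data, _ = simkit.simulate_dataset("null", n=300, seed=0)
        omega, table = baselines.cv_window_length(data, grid_s=np.array([60.0]))
        assert omega == 60.0
        assert len(table) == 1

    def test_constant_data_prefers_long_windows(self):
        hits = 0
        for seed in range(5):
            data, _ = simkit.simulate_dataset("constant", n=400, seed=20 + seed)
            omega, _ = baselines.cv_window_length(data)
            hits += omega >= 100.0
        assert hits >= 4

    def test_fast_dynamics_prefer_shorter_windows_paired(self):
        shorter = 0
        for seed in range(5):
            const, _ = simkit.simulate_dataset("constant", n=400, seed=30 + seed)
            fast, _ = simkit.simulate_dataset("periodic_fast", n=400, seed=30 + seed)
            w_c, _ = baselines.cv_window_length(const)
            w_f, _ = baselines.cv_window_length(fast)
            shorter += w_f < w_c
        assert shorter >= 4

    def test_true_covariance_scores_at_least_as_well(self):
        # likelihood-scoring calibration: the generating covariance upper-
        # bounds any window estimate's mean score, on average over trials
        diffs = []
        for seed in range(10):
            data, truth = simkit.simulate_dataset("periodic_slow", n=300, seed=50 + seed)
            _, table = baselines.cv_window_length(data)
            best_est = table["mean_loglik"].max()
            wmax = int(round(180.0 / data.tr))
            lo = wmax // 2
            idx = np.arange(lo, lo + data.n - wmax)
            sig = truth.sigmas[idx]
            sign, logdet = np.linalg.slogdet(sig)
            quad = np.einsum("ni,nij,nj->n", data.y[idx], np.linalg.inv(sig), data.y[idx])
            truth_score = np.mean(-math.log(2 * math.pi) - 0.5 * logdet - 0.5 * quad)
            diffs.append(truth_score - best_est)
        assert np.mean(diffs) > -0.01

    def test_series_too_short_rejected(self):
        data, _ = simkit.simulate_dataset("null", n=80, seed=0)
        with pytest.raises(ValueError, match="short"):
            baselines.cv_window_length(data)


class TestGarch:
    def test_iid_data_small_arch_terms(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(2000) * 1.7
        params, z = baselines.garch11_fit(y)
        assert params.a_arch + params.b_garch < 0.2
        assert abs(params.uncond_var - y.var()) / y.var() < 0.15
        assert abs(z.std() - 1.0) < 0.05

    def test_parameter_recovery(self):
        # simulate GARCH(1,1) with (a, b) = (0.1, 0.8)
        a_true, b_true, omega_true = 0.1, 0.8, 0.2
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 4000
            y = np.empty(n)
            h = omega_true / (1 - a_true - b_true)
            for t in range(n):
                y[t] = math.sqrt(h) * rng.standard_normal()
                h = omega_true + a_true * y[t] ** 2 + b_true * h
            params, _ = baselines.garch11_fit(y)
            # generous recovery bands (~95% sampling spread at N=4000)
            hits += abs(params.a_arch - a_true) < 0.05 and abs(params.b_garch - b_true) < 0.12
        assert hits >= 9

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            baselines.garch11_fit(np.ones(100))


class TestDcc:
    def test_zero_ab_recursion_is_unconditional_correlation(self, rng):
        z = rng.standard_normal((50, 3))
        qbar = np.corrcoef(z, rowvar=False)
        r = baselines.dcc_recursion(z, 0.0, 0.0, qbar)
        np.testing.assert_allclose(r, np.tile(qbar, (50, 1, 1)), atol=1e-8)

    def test_recursion_preserves_pd(self, rng):
        for _ in range(10):
            z = rng.standard_normal((80, 3))
            qbar = np.corrcoef(z, rowvar=False)
            a = rng.uniform(0, 0.3)
            b = rng.uniform(0, 0.6)
            r = baselines.dcc_recursion(z, a, b, qbar)
            assert np.linalg.eigvalsh(r).min() > 0

    def test_joint_equals_bivariate_loop_for_d2(self):
        data, _ = simkit.simulate_dataset("periodic_slow", n=300, seed=5)
        joint = baselines.dcc_tvfc(data, mode="joint")
        bl = baselines.dcc_tvfc(data, mode="bivariate_loop")
        np.testing.assert_allclose(joint.sigmas, bl.sigmas, atol=1e-8)

    def test_path_recovery_on_model_matched_data(self):
        qbar = np.array([[1.0, 0.4], [0.4, 1.0]])
        y, r_true = baselines.simulate_dcc(4000, qbar, a=0.05, b=0.9, seed=0)
        data = TimeSeriesData(y=y, tr=2.0)
        est = baselines.dcc_tvfc(data, mode="joint")
        corr = np.corrcoef(est.edge(0, 1), r_true[:, 0, 1])[0, 1]
        assert corr > 0.7

    def test_valid_correlation_output(self):
        data, _ = simkit.simulate_dataset("stepwise", n=300, seed=6, d=3, topology="sparse")
        for mode in ("joint", "bivariate_loop"):
            traj = baselines.dcc_tvfc(data, mode=mode)
            diag = np.diagonal(traj.sigmas, axis1=1, axis2=2)
            np.testing.assert_allclose(diag, 1.0)
            assert np.all(np.abs(traj.sigmas) <= 1.0 + 1e-12)
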