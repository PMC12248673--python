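"""ESKF tests: structure, equilibria, closed-form kinematics, and the
equivalence of the shared Kalman algebra with textbook recursions."""

import numpy as np
import pytest

from flightlfp import SimConfig
from flightlfp.config import GRAVITY, EskfConfig
from flightlfp.fusion import (ERROR_STATE_DIM, OBS_DIM, FilterModel,
                              LinearKalmanFilter, NominalState, gps_update,
                              joseph_update, kalman_gain,
                              predict_covariance, propagate, run_eskf)
from flightlfp.synthio import simulate_sensors, simulate_trajectory


def _level_state():
    return NominalState(q=np.array([0.0, 0.0, 0.0, 1.0]), v=np.zeros(3),
                        p=np.zeros(3), b_g=np.zeros(3), b_a=np.zeros(3))


def _model(dt=0.005):
    return FilterModel.from_config(EskfConfig(), dt)


class TestStructure:
    def test_error_state_and_observation_dimensions(self):
        model = _model()
        assert model.Q.shape == (ERROR_STATE_DIM, ERROR_STATE_DIM)
        assert model.H.shape == (OBS_DIM, ERROR_STATE_DIM)
        assert ERROR_STATE_DIM == 15 and OBS_DIM == 3

    def test_H_selects_position_block(self):
        model = _model()
        assert np.array_equal(model.H[:, :3], np.eye(3))
        assert not model.H[:, 3:].any()


class TestPropagate:
    def test_stationary_equilibrium(self):
        state, model = _level_state(), _model()
        P = np.eye(ERROR_STATE_DIM)
        f_static = np.array([0.0, 0.0, GRAVITY])  # specific force at rest
        for k in range(1, 100):
            state, P, a = propagate(state, P, model, f_static, np.zeros(3),
                                    t=k * 0.005, dt=0.005)
        assert np.allclose(state.p, 0.0, atol=1e-12)
        assert np.allclose(state.v, 0.0, atol=1e-12)
        assert np.allclose(a, 0.0, atol=1e-12)

    def test_identity_transition_zero_noise_keeps_covariance(self):
        P = np.diag(np.arange(1.0, 16.0))
        P2 = predict_covariance(P, np.eye(15), np.zeros((15, 15)))
        assert np.allclose(P, P2)

    def test_constant_acceleration_closed_form(self):
        """1 m/s^2 east for 10 s -> v = 10 m/s, x = 50 m (kinematics)."""
        state, model = _level_state(), _model()
        P = np.eye(ERROR_STATE_DIM)
        dt = 0.005
        f = np.array([1.0, 0.0, GRAVITY])
        for k in range(1, int(10 / dt) + 1):
            state, P, _ = propagate(state, P, model, f, np.zeros(3),
                                    t=k * dt, dt=dt)
        assert abs(state.v[0] - 10.0) < 1e-6
        assert abs(state.p[0] - 50.0) < 1e-3

    def test_rejects_non_increasing_time(self):
        state, model = _level_state(), _model()
        state.t = 1.0
        with pytest.raises(ValueError, match="increasing"):
            propagate(state, np.eye(15), model,
                      np.array([0, 0, GRAVITY]), np.zeros(3), t=0.5, dt=0.005)


class TestGpsUpdate:
    def test_zero_innovation_keeps_state(self):
        state, model = _level_state(), _model()
        P = 0.5 * np.eye(ERROR_STATE_DIM)
        new, _ = gps_update(state, P, model, np.zeros(3))
        assert np.allclose(new.p, state.p)
        assert np.allclose(new.v, state.v)
        assert np.allclose(new.q, state.q)

    def test_scalar_gain_closed_form(self):
        P = np.array([[2.0]])
        H = np.array([[1.0]])
        R = np.array([[3.0]])
        K = kalman_gain(P, H, R)
        assert abs(K[0, 0] - 2.0 / (2.0 + 3.0)) < 1e-12

    def test_uninformative_measurement_leaves_prediction(self):
        state, model = _level_state(), _model()
        model.R = 1e6 * np.eye(3)
        P = np.eye(ERROR_STATE_DIM)
        new, _ = gps_update(state, P, model, np.array([5.0, -3.0, 2.0]))
        assert np.allclose(new.p, state.p, atol=1e-4)

    def test_joseph_form_preserves_symmetry_psd(self, rng):
        for _ in range(20):
            A = rng.standard_normal((15, 15))
            P = A @ A.T + 1e-6 * np.eye(15)
            model = _model()
            K = kalman_gain(P, model.H, model.R)
            P2 = joseph_update(P, K, model.H, model.R)
            assert np.allclose(P2, P2.T)
            assert np.linalg.eigvalsh(P2).min() > -1e-10


class TestLinearEquivalence:
    def test_matches_textbook_kalman_to_1e9(self, rng):
        """1-D constant-velocity tracking vs an independent oracle."""
        dt = 0.1
        Phi = np.array([[1.0, dt], [0.0, 1.0]])
        H = np.array([[1.0, 0.0]])
        Q = np.diag([1e-4, 1e-3])
        R = np.array([[0.5]])
        kf = LinearKalmanFilter([0.0, 0.0], np.eye(2), Phi, H, Q, R)

        # textbook recursions, written independently of the filter class
        x = np.zeros(2)
        P = np.eye(2)
        for _ in range(100):
            z = rng.standard_normal()
            kf.predict()
            kf.update([z])
            x = Phi @ x
            P = Phi @ P @ Phi.T + Q
            S = H @ P @ H.T + R
            K = P @ H.T @ np.linalg.inv(S)
            x = x + (K @ (np.array([z]) - H @ x).reshape(1)).ravel()
            P = (np.eye(2) - K @ H) @ P
            assert np.abs(kf.x - x).max() < 1e-9
            assert np.abs(kf.P - P).max() < 1e-9


class TestRunEskf:
    def test_noiseless_recovery(self):
        cfg = SimConfig(duration_s=20, seed=1, accel_noise=0.0,
                        gyro_noise=0.0, gps_sigma=0.0,
                        accel_bias=(0, 0, 0), gyro_bias=(0, 0, 0),
                        wingbeat_amp=0.0, pitch_amp=0.0)
        truth = simulate_trajectory(cfg)
        rec = simulate_sensors(truth, cfg)
        nav = run_eskf(rec, EskfConfig(gps_sigma=0.01))
        rmse = np.sqrt(np.mean(
            (nav.accel_tangential - truth.accel_tangential) ** 2))
        assert rmse < 0.05

    def test_dead_reckoning_flag_and_covariance_growth(self):
        cfg = SimConfig(duration_s=15, seed=1)
        truth = simulate_trajectory(cfg)
        rec = simulate_sensors(truth, cfg)
        rec.gps_t = np.empty(0)
        rec.gps_enu = np.empty((0, 3))
        nav = run_eskf(rec)
        assert nav.dead_reckoning
        pos_trace = nav.cov_diag[:, :3].sum(axis=1)
        assert np.all(np.diff(pos_trace) > 0)

    def test_gps_gap_flagged_and_propagated_to_segments(self):
        from flightlfp.segmentation import segment_recording
        cfg = SimConfig(duration_s=20, seed=1)
        truth = simulate_trajectory(cfg)
        rec = simulate_sensors(truth, cfg)
        keep = (rec.gps_t < 8.0) | (rec.gps_t > 12.0)
        rec.gps_t, rec.gps_enu = rec.gps_t[keep], rec.gps_enu[keep]
        nav = run_eskf(rec)
        assert any(abs(lo - 7.9) < 0.2 for lo, hi in nav.gps_gap_intervals)
        segs = segment_recording(nav)
        flagged = [s for s in segs if "gps_gap" in s.qc_flags]
        assert flagged and all(s.start_s < 12.5 and s.end_s > 7.5
                               for s in flagged)

    def test_quaternion_norm_and_speed_invariants(self, flight120):
        nav = flight120["nav"]
        assert np.allclose(np.linalg.norm(nav.attitude, axis=1), 1.0,
                           atol=1e-9)
        assert np.allclose(nav.speed, np.linalg.norm(nav.velocity, axis=1))
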