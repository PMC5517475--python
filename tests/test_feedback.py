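import numpy as np
import pytest

from ailum.config import AcquisitionConfig, NoiseModel
from ailum.feedback import (MODE_FEEDBACK_ACTIVE, MODE_POWER_LIMITED,
                            PIDState, pid_step, run_pixel_dwell, scan_frame,
                            transition_strength)
from ailum.scenes import make_structural_scene


class TestPidStep:
    def test_proportional_only_arithmetic(self, cfg):
        pcfg = cfg.replace(Kp=2.0, Ki=0.0, Kd=0.0)
        u, state = pid_step(100.0, PIDState(), pcfg)
        assert u == 200.0
        assert state.prev_error == 100.0

    def test_zero_error_keeps_integral_bias(self, cfg):
        state = PIDState(integral=1e-4)
        u, _ = pid_step(0.0, state, cfg)
        assert u == pytest.approx(cfg.Ki * 1e-4)

    def test_output_clamped_to_dac_range(self, cfg):
        u, _ = pid_step(1e12, PIDState(), cfg.replace(Kp=1.0))
        assert u == 2**cfg.B_P
        u, _ = pid_step(-1e12, PIDState(), cfg.replace(Kp=1.0))
        assert u == 0.0

    def test_antiwindup_freezes_integrator_at_clamp(self, cfg):
        state = PIDState()
        for _ in range(5):
            u, state = pid_step(100.0, state, cfg)   # charge within range
        assert 0.0 < u < 2**cfg.B_P
        charged = state.integral
        for _ in range(20):
            _, state = pid_step(1e9, state, cfg)     # railed high: frozen
        assert state.integral == charged
        _, state = pid_step(-100.0, state, cfg)      # opposite error unwinds
        assert state.integral < charged

    def test_nonfinite_state_rejected(self, cfg):
        with pytest.raises(ValueError):
            pid_step(np.nan, PIDState(), cfg)
        with pytest.raises(ValueError):
            pid_step(1.0, PIDState(integral=np.inf), cfg)

    def test_integral_action_removes_steady_state_error(self, cfg):
        # discrete-time oracle: linear plant S_hat = k*u, >=1e3 steps
        k = 1.0
        pcfg = cfg.replace(Kp=0.0, Ki=0.5 / cfg.dt_substep, Kd=0.0)
        target = 3000.0
        state = PIDState()
        u = 0.0
        for _ in range(1000):
            e = target - k * u
            u, state = pid_step(e, state, pcfg)
        assert target - k * u == pytest.approx(0.0, abs=1e-6)


class TestPixelDwell:
    def test_feedback_active_steady_state(self, cfg, noiseless):
        # closed form: P = (S0/X)**(1/alpha), S = S0
        tr = run_pixel_dwell(500.0, cfg, noiseless)
        assert tr.mode == MODE_FEEDBACK_ACTIVE
        assert tr.S_series[-1] == pytest.approx(125.0, rel=0.02)
        assert tr.P_actual_series[-1] == pytest.approx(0.5, rel=0.02)

    def test_power_limited_steady_state(self, cfg, noiseless):
        tr = run_pixel_dwell(31.25, cfg, noiseless)
        assert tr.mode == MODE_POWER_LIMITED
        assert tr.P_actual_series[-1] == pytest.approx(1.0)
        assert tr.S_series[-1] == pytest.approx(31.25, rel=0.01)

    def test_dark_pixel_rails_at_max_power(self, cfg, noiseless):
        tr = run_pixel_dwell(0.0, cfg, noiseless)
        assert tr.mode == MODE_POWER_LIMITED
        assert tr.S_series[-1] == 0.0
        assert tr.P_hat == 2**cfg.B_P

    def test_power_never_exceeds_ceiling(self, cfg, noiseless, shot):
        for X in (0.0, 10.0, 500.0, 1e5, 1e7):
            for noise in (noiseless, shot):
                tr = run_pixel_dwell(X, cfg, noise, seed=3)
                assert tr.P_command_series.max() <= cfg.P_max + 1e-12
                assert tr.P_actual_series.max() <= cfg.P_max + 1e-12

    def test_detector_protection_in_steady_state(self, cfg, noiseless):
        # noise-free: S never held above S0 (+2% settling tolerance)
        for X in (130.0, 500.0, 1e4, 1e6):
            tr = run_pixel_dwell(X, cfg, noiseless, seed=0)
            assert tr.S_series[-1] <= cfg.S0 * 1.02

    def test_mode_boundary_at_transition_strength(self, cfg, noiseless):
        x_t = transition_strength(cfg)
        assert x_t == 125.0
        for X, expected in ((x_t * 0.8, MODE_POWER_LIMITED),
                            (x_t * 1.3, MODE_FEEDBACK_ACTIVE)):
            tr = run_pixel_dwell(X, cfg, noiseless)
            assert tr.mode == expected

    def test_determinism_and_input_validation(self, cfg, shot):
        a = run_pixel_dwell(300.0, cfg, shot, seed=5)
        b = run_pixel_dwell(300.0, cfg, shot, seed=5)
        assert np.array_equal(a.S_series, b.S_series)
        assert a.S_hat == b.S_hat and a.P_hat == b.P_hat
        with pytest.raises(ValueError):
            run_pixel_dwell(-1.0, cfg, shot)


class TestTransitionStrength:
    def test_values_and_scaling(self, cfg):
        assert transition_strength(cfg) == 125.0
        assert transition_strength(cfg.replace(P_max=2.0)) == 125.0 / 4
        assert transition_strength(cfg.replace(alpha=1)) == 125.0


class TestScanFrame:
    def test_conventional_flags_saturated_pixels(self, cfg, noiseless):
        scene = np.array([[10.0, 400.0], [100.0, 1e5]])
        rec = scan_frame(scene, cfg, noiseless, mode="conventional")
        assert rec.clip_map.tolist() == [[False, True], [False, True]]
        assert np.all(rec.S_hat_map <= 2**cfg.B - 1)

    def test_ai_constant_scene_settles_to_identical_pixels(self, cfg, noiseless):
        scene = np.full((4, 16), 600.0)
        rec = scan_frame(scene, cfg, noiseless, mode="ai")
        flat_S = rec.S_hat_map.ravel()
        flat_P = rec.P_hat_map.ravel()
        assert np.all(flat_S[1:] == flat_S[1])
        assert np.all(flat_P[1:] == flat_P[1])

    def test_ai_power_code_bounded(self, cfg, shot):
        scene = make_structural_scene((48, 48), 1e6, seed=0).strength
        rec = scan_frame(scene, cfg, shot, mode="ai", seed=2)
        assert rec.P_hat_map.max() <= 2**cfg.B_P
        assert rec.P_hat_map.min() >= 1

    def test_mode_map_matches_transition_strength(self, cfg, noiseless):
        x_t = transition_strength(cfg)
        scene = np.array([[x_t / 4, x_t * 4, x_t * 100, 0.0]])
        rec = scan_frame(scene, cfg, noiseless, mode="ai")
        assert rec.mode_map.tolist() == [[1, 0, 0, 1]]

    def test_unknown_mode_rejected(self, cfg):
        with pytest.raises(ValueError, match="unknown scan mode"):
            scan_frame(np.ones((4, 4)), cfg, mode="fancy")

    def test_per_pixel_reset_option(self, cfg, noiseless):
        scene = np.full((2, 8), 600.0)
        rec = scan_frame(scene, cfg.replace(carry_over=False), noiseless,
                         mode="ai")
        assert np.all(rec.S_hat_map == rec.S_hat_map[0, 0])
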