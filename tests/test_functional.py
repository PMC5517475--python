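import numpy as np
import pytest
from scipy.stats import spearmanr

from ailum.config import AcquisitionConfig, NoiseModel
from ailum.feedback import scan_frame
from ailum.functional import (ROITrace, activity_map, clip_mask, cohort_summary,
                              compute_f0, delta_f_over_f, extract_roi_traces,
                              response_stats)
from ailum.pipeline import acquire_movie
from ailum.scenes import make_functional_scene


class TestBaselineAndDff:
    def test_constant_trace_baseline(self):
        t = np.arange(50) * 0.1
        assert compute_f0(np.full(50, 100.0), t, (0.0, 2.0)) == 100.0

    def test_single_frame_window(self):
        t = np.arange(5) * 1.0
        F = np.array([7.0, 9.0, 11.0, 13.0, 15.0])
        assert compute_f0(F, t, (1.0, 1.0)) == 9.0

    def test_noisy_baseline_converges_to_true_mean(self, rng):
        n = 10_000
        F = 100.0 + rng.normal(0, 5.0, size=n)
        t = np.arange(n) * 0.01
        f0 = compute_f0(F, t, (0.0, t[-1]))
        assert abs(f0 - 100.0) <= 3 * 5.0 / np.sqrt(n)

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(10) * 0.1
        with pytest.raises(ValueError, match="F0"):
            compute_f0(np.zeros(10), t, (0.0, 0.5))
        with pytest.raises(ValueError):
            delta_f_over_f([1.0], 0.0)

    def test_dff_values_including_decreases(self):
        assert delta_f_over_f([150.0], 100.0)[0] == 0.5
        assert delta_f_over_f([80.0], 100.0)[0] == -0.2
        assert delta_f_over_f([100.0], 100.0)[0] == 0.0


class TestActivityMap:
    def _movie(self, amps, dt=0.2, n_frames=50, onset=3.0):
        fs = make_functional_scene((48, 48), n_rois=len(amps), amp_spec=amps,
                                   dt=dt, n_frames=n_frames, stim_onset=onset,
                                   seed=2)
        return fs, fs.frames()

    def test_matches_kernel_average_over_window(self):
        fs, movie = self._movie([1.0])
        amap = activity_map(movie, fs.dt, fs.stim_onset, window_s=5.0)
        t = fs.times
        w = (t >= fs.stim_onset) & (t <= fs.stim_onset + 5.0)
        expected = fs.dff_traces[0, w].mean()    # closed-form kernel mean
        roi = fs.roi_ids == 1
        assert amap[roi] == pytest.approx(expected, abs=1e-9)

    def test_no_stimulus_map_is_zero_and_sign_preserved(self):
        fs, movie = self._movie([0.0, -0.3])
        amap = activity_map(movie, fs.dt, fs.stim_onset)
        assert np.nanmax(np.abs(amap[fs.roi_ids == 1])) == 0.0
        assert np.all(amap[fs.roi_ids == 2] < 0)

    def test_background_masked_and_window_validated(self):
        fs, movie = self._movie([0.5])
        amap = activity_map(movie, fs.dt, fs.stim_onset)
        assert np.isnan(amap[fs.roi_ids == 0]).all()
        with pytest.raises(ValueError, match="past the recording"):
            activity_map(movie, fs.dt, fs.stim_onset, window_s=100.0)


class TestClipMask:
    def test_any_frame_semantics(self):
        clips = np.zeros((5, 4, 4), dtype=bool)
        assert not clip_mask(clips).any()
        clips[3, 1, 2] = True
        mask = clip_mask(clips)
        assert mask[1, 2] and mask.sum() == 1

    def test_monotone_in_conventional_power(self, cfg, noiseless):
        scene = np.geomspace(1.0, 1e4, 64).reshape(8, 8)
        low = scan_frame(scene, cfg.replace(P0=0.3), noiseless,
                         mode="conventional")
        high = scan_frame(scene, cfg.replace(P0=1.0), noiseless,
                          mode="conventional")
        assert low.clip_map.sum() > 0
        assert np.all(high.clip_map >= low.clip_map)   # never shrinks


class TestResponseStats:
    def _trace(self, dff, dt=0.1, onset=2.0):
        t = np.arange(len(dff)) * dt
        return ROITrace(roi_id=1, t=t, F=100 * (1 + np.asarray(dff)), F0=100.0,
                        dff=np.asarray(dff, float), rest_window=(0.0, onset - 0.5),
                        response_window=(onset, t[-1]))

    def test_snr_is_peak_over_rest_sd(self, rng):
        dff = np.concatenate([rng.normal(0, 0.05, 20), [0.5], np.zeros(9)])
        stats = response_stats(self._trace(dff))
        assert stats.snr == pytest.approx(stats.peak_dff / stats.rest_sd)
        assert stats.sign == "increase"

    def test_suppressed_response_gets_negative_peak(self, rng):
        dff = np.concatenate([rng.normal(0, 0.02, 20), [-0.4], np.zeros(9)])
        stats = response_stats(self._trace(dff))
        assert stats.peak_dff == -0.4
        assert stats.sign == "decrease" and stats.snr < 0

    def test_zero_rest_sd_flagged_infinite(self):
        dff = np.concatenate([np.zeros(20), [0.3], np.zeros(9)])
        stats = response_stats(self._trace(dff))
        assert np.isinf(stats.snr) and stats.snr_infinite


class TestPipelineRecovery:
    def test_rank_order_of_roi_snr_recovered(self, cfg):
        # 30 ROIs, amplitudes spanning 0.05-2.0, acquired through the full
        # AI pipeline with shot noise
        amps = np.geomspace(0.05, 2.0, 30)
        fs = make_functional_scene((64, 64), n_rois=30, amp_spec=amps,
                                   seed=5, roi_radius=3)
        noise = NoiseModel(shot_noise=True, pd_sigma=0.001)
        movie, _ = acquire_movie(fs, cfg, noise, mode="ai", seed=20)
        traces = extract_roi_traces(movie, fs.roi_ids, fs.dt, fs.stim_onset)
        table = cohort_summary([response_stats(tr) for tr in traces])
        truth = amps / table["rest_sd"].values   # expected SNR ordering
        rho = spearmanr(table["snr"].values, truth).statistic
        assert rho >= 0.9

    def test_dff_invariant_to_global_reconstruction_scale(self):
        fs = make_functional_scene((48, 48), n_rois=3, amp_spec=[0.8, -0.2, 0.3],
                                   seed=1)
        movie = fs.frames()
        tr_a = extract_roi_traces(movie, fs.roi_ids, fs.dt, fs.stim_onset)
        tr_b = extract_roi_traces(movie * 1234.5, fs.roi_ids, fs.dt,
                                  fs.stim_onset)
        for a, b in zip(tr_a, tr_b):
            assert np.allclose(a.dff, b.dff)
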