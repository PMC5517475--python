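import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ailum.scenes import (CLASS_NAMES, LABEL_SOMA, SceneMap,
                          ground_truth_summary, make_functional_scene,
                          make_structural_scene)


class TestStructuralScene:
    @pytest.mark.parametrize("ratio", [1.0, 10.0, 1e4, 1e8, 1e10])
    def test_requested_brightness_ratio_achieved(self, ratio):
        scene = make_structural_scene((64, 64), ratio, seed=3)
        assert scene.achieved_ratio == pytest.approx(ratio, rel=0.01)
        assert (scene.strength >= 0).all()

    def test_degenerate_ratio_gives_constant_structures(self):
        scene = make_structural_scene((64, 64), 1.0, seed=0, peak_strength=5.0)
        pos = scene.strength[scene.strength > 0]
        assert pos.size > 0
        assert np.all(pos == 5.0)

    def test_same_seed_bit_identical(self):
        a = make_structural_scene((64, 64), 1e6, seed=7)
        b = make_structural_scene((64, 64), 1e6, seed=7)
        assert np.array_equal(a.strength, b.strength)
        assert np.array_equal(a.labels, b.labels)
        c = make_structural_scene((64, 64), 1e6, seed=8)
        assert not np.array_equal(a.strength, c.strength)

    def test_labels_cover_every_positive_pixel(self):
        scene = make_structural_scene((96, 96), 1e8, seed=1)
        assert np.array_equal(scene.labels > 0, scene.strength > 0)
        present = {CLASS_NAMES[v] for v in np.unique(scene.labels) if v > 0}
        assert {"soma", "dendrite", "spine"} <= present

    def test_morphology_somas_bright_spines_dim(self):
        scene = make_structural_scene((96, 96), 1e6, seed=2, peak_strength=1e6)
        soma = scene.strength[scene.labels == 1]
        spine = scene.strength[scene.labels == 3]
        assert soma.min() == scene.strength.max()
        assert spine.max() == scene.min_positive

    def test_invalid_requests_rejected(self):
        with pytest.raises(ValueError, match="range_ratio"):
            make_structural_scene((64, 64), 0.5)
        with pytest.raises(ValueError, match="32x32"):
            make_structural_scene((16, 16), 10.0)
        with pytest.raises(ValueError, match="capacity"):
            make_structural_scene((48, 48), 10.0, counts={"soma": 500})

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(ratio=st.floats(min_value=1.0, max_value=1e10),
           seed=st.integers(min_value=0, max_value=2**16))
    def test_ratio_property_over_range(self, ratio, seed):
        scene = make_structural_scene((48, 48), ratio, seed=seed)
        assert scene.achieved_ratio == pytest.approx(ratio, rel=0.01)
        assert scene.strength.min() >= 0


class TestFunctionalScene:
    def test_unit_amplitude_gives_unit_peak_dff(self):
        fs = make_functional_scene((48, 48), n_rois=3, amp_spec=[1.0, -0.3, 0.0],
                                   seed=0)
        mask = fs.roi_ids == 1
        base = fs.baseline.strength[mask].mean()
        peaks = np.array([fs.frame(f)[mask].mean() for f in range(fs.n_frames)])
        assert (peaks.max() - base) / base == pytest.approx(1.0, abs=1e-6)

    def test_negative_amplitude_dips_below_baseline(self):
        fs = make_functional_scene((48, 48), n_rois=2, amp_spec=[-0.3, 0.5],
                                   seed=1)
        mask = fs.roi_ids == 1
        base = fs.baseline.strength[mask].mean()
        trough = min(fs.frame(f)[mask].mean() for f in range(fs.n_frames))
        assert (trough - base) / base == pytest.approx(-0.3, abs=1e-6)
        assert fs.frames().min() >= 0.0

    def test_zero_amplitude_trace_constant(self):
        fs = make_functional_scene((48, 48), n_rois=1, amp_spec=[0.0], seed=2)
        movie = fs.frames()
        assert np.array_equal(movie[0], movie[-1])
        assert np.ptp(movie, axis=0).max() == 0.0

    def test_pre_stimulus_frames_are_baseline(self):
        fs = make_functional_scene((48, 48), n_rois=4, seed=3, stim_onset=3.0)
        pre = fs.times < fs.stim_onset
        assert pre.any()
        for f in np.nonzero(pre)[0]:
            assert np.array_equal(fs.frame(f), fs.baseline.strength)

    def test_invalid_requests_rejected(self):
        with pytest.raises(ValueError, match="negative strength"):
            make_functional_scene((48, 48), n_rois=2, amp_spec=[-1.5, 0.1])
        with pytest.raises(ValueError, match="5 s"):
            make_functional_scene((48, 48), n_frames=10, dt=0.2, stim_onset=3.0)

    def test_determinism(self):
        a = make_functional_scene((48, 48), n_rois=5, seed=11)
        b = make_functional_scene((48, 48), n_rois=5, seed=11)
        assert np.array_equal(a.frames(), b.frames())
        assert np.array_equal(a.response_amplitudes, b.response_amplitudes)


class TestGroundTruthSummary:
    def test_single_disk_mean(self):
        strength = np.zeros((40, 40))
        labels = np.zeros((40, 40), dtype=np.int8)
        strength[10, 10:20] = 5.0
        labels[10, 10:20] = LABEL_SOMA
        scene = SceneMap(strength=strength, labels=labels, seed=0)
        table = ground_truth_summary(scene)
        assert len(table) == 1
        assert table.iloc[0]["mean_strength"] == 5.0
        assert table.iloc[0]["n_pixels"] == 10

    def test_counts_reflected_in_rows(self):
        scene = make_structural_scene(
            (64, 64), 100.0, counts={"soma": 3, "dendrite": 0, "spine": 0},
            seed=0)
        table = ground_truth_summary(scene)
        assert (table["class"] == "soma").sum() == 3

    def test_functional_amplitudes_match_draws(self):
        fs = make_functional_scene((48, 48), n_rois=6, seed=4)
        table = ground_truth_summary(fs)
        assert np.allclose(table["amplitude"].values, fs.response_amplitudes)

    def test_empty_scene_empty_table(self):
        scene = SceneMap(strength=np.zeros((40, 40)),
                         labels=np.zeros((40, 40), dtype=np.int8), seed=0)
        assert len(ground_truth_summary(scene)) == 0
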