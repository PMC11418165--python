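"""Generator contracts: determinism, waveform structure, ground truth."""

import numpy as np
import pytest
from scipy.signal import find_peaks, hilbert

from geckovox import kinematics as kin
from geckovox import synth
from geckovox.audio import CALL_TYPES


class TestSynthCall:
    def test_same_seed_bit_identical(self):
        p = synth.SynthCallParams(call_type="type2", seed=11)
        a = synth.synth_call(p)
        b = synth.synth_call(p)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_pulse_count_matches_rate_when_unjittered(self):
        # 20 pulses/s over 0.5 s with zero jitter -> exactly 10 envelope peaks
        p = synth.SynthCallParams(call_type="type3", pulse_rate_hz=20.0,
                                  duration_s=0.5, pulse_jitter_cv=0.0,
                                  snr_db=None)
        clip = synth.synth_call(p)
        env = np.abs(hilbert(clip.samples))
        peaks, _ = find_peaks(env, height=0.3 * env.max(),
                              distance=int(0.02 * clip.sample_rate_hz))
        assert len(peaks) == 10

    def test_peak_amplitude_normalized(self):
        for ct in CALL_TYPES:
            clip = synth.synth_call(synth.SynthCallParams(call_type=ct, seed=3))
            assert np.max(np.abs(clip.samples)) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [
        dict(duration_s=0.0), dict(duration_s=-1.0),
        dict(sample_rate_hz=0.0), dict(mix_fraction=1.5),
        dict(call_type="type9"),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            synth.synth_call(synth.SynthCallParams(**bad))


class TestSynthCallDataset:
    def test_minimal_dataset_has_three_labeled_clips(self):
        clips = synth.synth_call_dataset(1, 1, seed=0)
        assert len(clips) == 3
        assert sorted(c.call_type for c in clips) == sorted(CALL_TYPES)
        assert all(c.individual_id == "ind1" for c in clips)

    def test_seed_changes_waveforms_not_label_structure(self):
        a = synth.synth_call_dataset(2, 2, seed=1)
        b = synth.synth_call_dataset(2, 2, seed=2)
        assert [(c.individual_id, c.call_type) for c in a] == \
            [(c.individual_id, c.call_type) for c in b]
        assert any(len(x) != len(y) or not np.array_equal(x.samples, y.samples)
                   for x, y in zip(a, b))

    def test_rejects_degenerate_sizes(self):
        with pytest.raises(ValueError):
            synth.synth_call_dataset(0, 1)


class TestSynthKinematics:
    def test_noiseless_single_event_round_trip(self):
        # configured excursion recovered exactly from the raw series
        p = synth.kinematic_defaults(
            "vocalization", "dorsal", n_events=1, noise_cm=0.0, seed=1,
            mean_displacement_cm=0.5, sd_displacement_cm=0.0,
            mean_cycle_s=0.9, sd_cycle_s=0.0,
        )
        res = synth.synth_kinematic_sequence(p)
        events = kin.extract_events(kin.compute_series(res.track),
                                    "vocalization")
        assert len(events) == 1
        assert events[0].total_movement_cm == pytest.approx(0.5, abs=1e-3)
        one_frame = 1.0 / p.frame_rate_hz
        assert events[0].cycle_duration_s == pytest.approx(0.9, abs=one_frame)

    def test_drawn_amplitudes_converge_to_configured(self):
        # generator-side calibration: sample moments at n=500 within 3 sem
        p = synth.kinematic_defaults("vocalization", "dorsal",
                                     n_events=500, seed=4)
        res = synth.synth_kinematic_sequence(p)
        amps = res.events["amplitude_cm"].to_numpy()
        sem = amps.std(ddof=1) / np.sqrt(len(amps))
        assert abs(amps.mean() - p.mean_displacement_cm) < 3 * sem
        durs = res.events["duration_s"].to_numpy()
        sem_d = durs.std(ddof=1) / np.sqrt(len(durs))
        assert abs(durs.mean() - p.mean_cycle_s) < 3 * sem_d

    def test_breathing_cycles_slower_than_vocalization(self):
        br = synth.synth_kinematic_sequence(
            synth.kinematic_defaults("breathing", "dorsal",
                                     n_events=200, seed=6))
        vo = synth.synth_kinematic_sequence(
            synth.kinematic_defaults("vocalization", "dorsal",
                                     n_events=200, seed=6))
        assert br.events["duration_s"].mean() > vo.events["duration_s"].mean()

    def test_deterministic_under_seed(self):
        p = synth.kinematic_defaults("breathing", "lateral",
                                     n_events=3, seed=9)
        a = synth.synth_kinematic_sequence(p)
        b = synth.synth_kinematic_sequence(p)
        np.testing.assert_array_equal(a.track.coords_cm, b.track.coords_cm)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synth.synth_kinematic_sequence(
                synth.kinematic_defaults("breathing", "dorsal",
                                         noise_cm=-0.1))


class TestSynthSoma:
    def test_circle_ground_truth_geometry(self):
        p = synth.SynthSomaParams(
            n_somata=1, mean_min_diam_um=20.0, sd_min_diam_um=0.0,
            mean_axis_ratio=1.0, sd_axis_ratio=0.0, um_per_px=1.0,
            image_size_px=64, seed=0,
        )
        res = synth.synth_soma_masks(p)
        row = res.truth.iloc[0]
        assert row.min_diam_um == pytest.approx(20.0)
        assert row.max_diam_um == pytest.approx(20.0)
        assert row.area_um2 == pytest.approx(np.pi * 100, abs=0.01)

    def test_ellipse_ground_truth_axes(self):
        p = synth.SynthSomaParams(
            n_somata=1, mean_min_diam_um=10.0, sd_min_diam_um=0.0,
            mean_axis_ratio=2.0, sd_axis_ratio=0.0, um_per_px=1.0,
            image_size_px=64, seed=0,
        )
        res = synth.synth_soma_masks(p)
        row = res.truth.iloc[0]
        assert row.min_diam_um == pytest.approx(10.0)
        assert row.max_diam_um == pytest.approx(20.0)

    def test_label_count_and_determinism(self):
        p = synth.SynthSomaParams(n_somata=5, image_size_px=512, seed=2)
        a = synth.synth_soma_masks(p)
        b = synth.synth_soma_masks(p)
        assert set(np.unique(a.labels)) == set(range(6))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_capacity_error_when_regions_cannot_fit(self):
        p = synth.SynthSomaParams(n_somata=50, mean_min_diam_um=30.0,
                                  image_size_px=128, seed=0)
        with pytest.raises(RuntimeError, match="place"):
            synth.synth_soma_masks(p)
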