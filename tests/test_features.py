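"""Cepstral front end, deltas, feature assembly and PCA contracts."""

import numpy as np
import pytest

from geckovox import features as feat
from geckovox.audio import AudioClip


class TestMelFilterbank:
    def test_mel_scale_closed_form(self):
        # mel(700) = 2595 log10(2)
        assert feat.hz_to_mel(700.0) == pytest.approx(2595 * np.log10(2))
        assert feat.hz_to_mel(0.0) == 0.0
        assert feat.mel_to_hz(feat.hz_to_mel(1234.5)) == pytest.approx(1234.5)

    def test_filters_supported_within_band_edges(self):
        fb = feat.build_mel_filterbank(20, 250.0, 5000.0, 4096, 44100.0)
        freqs = np.fft.rfftfreq(4096, d=1 / 44100.0)
        active = np.any(fb.weights > 0, axis=0)
        assert freqs[active].min() >= 250.0 - 44100 / 4096
        assert freqs[active].max() <= 5000.0 + 44100 / 4096
        assert np.all(fb.weights >= 0)
        assert np.all(np.diff(fb.centers_hz) > 0)

    def test_fmax_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            feat.build_mel_filterbank(20, 250.0, 30000.0, 4096, 44100.0)


class TestMFCC:
    def test_shape_is_segments_by_coefficients(self, call_dataset):
        mfcc = feat.compute_mfcc(call_dataset[0])
        assert mfcc.shape == (20, 15)

    def test_gain_moves_only_coefficient_zero(self):
        rng = np.random.default_rng(3)
        clip = AudioClip(rng.normal(size=44100), 44100.0)
        a = feat.compute_mfcc(clip)
        b = feat.compute_mfcc(clip.with_samples(clip.samples * 10))
        np.testing.assert_allclose(a[:, 1:], b[:, 1:], atol=1e-8)
        assert not np.allclose(a[:, 0], b[:, 0])

    def test_flat_mel_energies_give_zero_higher_coefficients(self):
        # all-zero signal -> every mel energy at the log floor -> the DCT
        # of a constant loads coefficient 0 only
        clip = AudioClip(np.zeros(44100), 44100.0)
        mfcc = feat.compute_mfcc(clip)
        np.testing.assert_allclose(mfcc[:, 1:], 0.0, atol=1e-10)

    def test_too_short_clip_rejected(self):
        with pytest.raises(ValueError):
            feat.compute_mfcc(AudioClip(np.ones(10), 44100.0))


class TestDeltas:
    def test_constant_column_has_zero_slope(self):
        deltas = feat.delta_coefficients(np.full((10, 3), 7.0))
        np.testing.assert_allclose(deltas, 0.0)

    @pytest.mark.parametrize("slope", [1.0, -2.0])
    def test_linear_ramp_recovers_slope_in_interior(self, slope):
        t = np.arange(12, dtype=float)
        mfcc = np.outer(slope * t, np.ones(2))
        deltas = feat.delta_coefficients(mfcc, window=2)
        np.testing.assert_allclose(deltas[2:-2], slope, atol=1e-12)

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError):
            feat.delta_coefficients(np.ones((1, 5)))


class TestFeatureVector:
    def test_length_is_560_after_mfcc0_exclusion(self, call_dataset):
        cf = feat.call_features(call_dataset[0])
        assert cf.feature_vector.shape == (560,)

    def test_mfcc0_perturbation_leaves_vector_unchanged(self, call_dataset):
        cf = feat.call_features(call_dataset[0])
        perturbed = feat.CallFeatures(mfcc=cf.mfcc.copy(),
                                      deltas=cf.deltas.copy())
        perturbed.mfcc[:, 0] += 99.0
        perturbed.deltas[:, 0] -= 5.0
        np.testing.assert_array_equal(cf.feature_vector,
                                      perturbed.feature_vector)

    def test_amplitude_scaling_invariance_end_to_end(self, call_dataset):
        clip = call_dataset[1]
        a = feat.call_features(clip).feature_vector
        b = feat.call_features(clip.with_samples(clip.samples * 0.1)
                               ).feature_vector
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            feat.assemble_feature_vector(
                feat.CallFeatures(mfcc=np.ones((20, 15)),
                                  deltas=np.ones((19, 15))))


class TestPCA:
    def test_collinear_points_explained_by_one_component(self):
        t = np.linspace(0, 1, 30)
        X = np.outer(t, [1.0, -2.0, 0.5])
        res = feat.run_pca(X)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 4))
        res = feat.run_pca(X)
        # independent oracle: eigendecomposition of the covariance matrix
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(
            res.explained_variance_fraction,
            np.maximum(evals, 0) / evals.sum(), atol=1e-10)
        for j in range(res.loadings.shape[1]):
            dot = abs(np.dot(res.loadings[:, j], evecs[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 7))
        res = feat.run_pca(X)
        Xc = X - res.mean
        recon = res.scores @ res.loadings.T
        err = np.linalg.norm(Xc - recon) / np.linalg.norm(Xc)
        assert err < 1e-8
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0)

    def test_explained_fractions_non_increasing(self):
        rng = np.random.default_rng(7)
        res = feat.run_pca(rng.normal(size=(20, 6)))
        assert np.all(np.diff(res.explained_variance_fraction) <= 1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            feat.run_pca(np.ones((1, 4)))


class TestClusterSeparation:
    def test_well_separated_blobs_have_high_silhouettes(self):
        rng = np.random.default_rng(8)
        a = rng.normal([0, 0, 0], 0.1, size=(30, 3))
        b = rng.normal([5, 5, 5], 0.1, size=(30, 3))
        sil = feat.cluster_separation(np.vstack([a, b]),
                                      ["a"] * 30 + ["b"] * 30)
        assert sil["a"] > 0.5 and sil["b"] > 0.5

    def test_single_member_label_undefined(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 3))
        sil = feat.cluster_separation(X, ["a", "a", "a", "a", "b"])
        assert np.isnan(sil["b"])

    def test_fewer_than_two_labels_rejected(self):
        with pytest.raises(ValueError):
            feat.cluster_separation(np.ones((4, 3)), ["a"] * 4)


class TestTypeSeparationOnSyntheticCalls:
    def test_type2_is_the_overlapping_cloud(self, call_dataset):
        # the intermediate type blends the two pure waveforms, so its
        # silhouette must be the lowest of the three
        clips = [c for c in call_dataset
                 if c.duration_s >= feat.MIN_PCA_DURATION_S]
        fb = feat.build_mel_filterbank()
        X = np.stack([feat.call_features(c, fb=fb).feature_vector
                      for c in clips])
        res = feat.run_pca(X, n_components=3)
        sil = feat.cluster_separation(res.scores,
                                      [c.call_type for c in clips])
        assert sil["type2"] < min(sil["type1"], sil["type3"])
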