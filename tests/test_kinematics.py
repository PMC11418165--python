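"""Distance signals, event extraction, behavior contrast, coupling."""

import numpy as np
import pytest

from geckovox import kinematics as kin
from geckovox import synth
from geckovox.kinematics import MARKERS, KinematicSeries, MarkerTrack


def make_track(larynx_xy, view="dorsal", frame_rate=200.0, **marker_xy):
    """Track with static markers except an explicit larynx trajectory."""
    larynx = np.asarray(larynx_xy, dtype=float)
    n = larynx.shape[0]
    coords = np.zeros((n, len(MARKERS), 2))
    defaults = {
        "upper_jaw_anterior": (4.0, 0.3),
        "upper_jaw_posterior": (0.5, 0.9),
        "lower_jaw_anterior": (4.0, -0.3),
        "lower_jaw_posterior": (0.5, -0.9),
    }
    defaults.update(marker_xy)
    for m, name in enumerate(MARKERS):
        if name == "larynx":
            coords[:, m, :] = larynx
        else:
            coords[:, m, :] = defaults[name]
    return MarkerTrack(view=view, frame_rate_hz=frame_rate, coords_cm=coords)


class TestSmoothTrack:
    def test_constant_trajectory_unchanged(self):
        track = make_track(np.tile([1.0, 0.0], (500, 1)))
        out = kin.smooth_track(track)
        np.testing.assert_allclose(out.coords_cm, track.coords_cm, atol=1e-9)

    def test_slow_sinusoid_amplitude_preserved(self):
        t = np.arange(2000) / 200.0
        lar = np.column_stack([1.0 + 0.5 * np.sin(2 * np.pi * 2 * t),
                               np.zeros_like(t)])
        out = kin.smooth_track(make_track(lar), cutoff_hz=10.0, order=4)
        mid = slice(400, 1600)
        x = out.coords_cm[mid, MARKERS.index("larynx"), 0]
        assert np.ptp(x) == pytest.approx(1.0, rel=0.01)

    def test_fast_jitter_attenuated_per_analytic_response(self):
        t = np.arange(2000) / 200.0
        jitter = 0.1 * np.sin(2 * np.pi * 50 * t)
        lar = np.column_stack([1.0 + jitter, np.zeros_like(t)])
        out = kin.smooth_track(make_track(lar), cutoff_hz=10.0, order=4)
        x = out.coords_cm[400:1600, MARKERS.index("larynx"), 0] - 1.0
        # forward-backward 4th-order low-pass: |H(50)|^2 with fc=10
        bound = (1.0 / np.sqrt(1 + (50 / 10) ** 8)) ** 2
        assert np.max(np.abs(x)) <= 0.1 * bound * 10

    def test_cutoff_at_nyquist_rejected(self):
        track = make_track(np.tile([1.0, 0.0], (100, 1)))
        with pytest.raises(ValueError):
            kin.smooth_track(track, cutoff_hz=100.0)


class TestComputeSeries:
    def test_pythagorean_distance(self):
        track = make_track(np.tile([3.0, 4.0], (10, 1)),
                           lower_jaw_anterior=(0.0, 0.0))
        series = kin.compute_series(track)
        np.testing.assert_allclose(series.larynx_cm, 5.0)

    def test_coincident_markers_distance_zero(self):
        track = make_track(np.tile([4.0, -0.3], (10, 1)))
        series = kin.compute_series(track)
        np.testing.assert_allclose(series.larynx_cm, 0.0, atol=1e-12)

    def test_view_selects_axis(self):
        dorsal = kin.compute_series(make_track(np.tile([1.0, 0.0], (5, 1)),
                                               view="dorsal"))
        lateral = kin.compute_series(make_track(np.tile([1.0, 0.2], (5, 1)),
                                                view="lateral"))
        assert dorsal.axis == "antero_posterior"
        assert lateral.axis == "dorso_ventral"

    def test_gape_is_anterior_marker_distance(self):
        track = make_track(np.tile([1.0, 0.0], (5, 1)),
                           upper_jaw_anterior=(4.0, 1.0),
                           lower_jaw_anterior=(4.0, -1.0))
        series = kin.compute_series(track)
        np.testing.assert_allclose(series.gape_cm, 2.0)


def _series(x, frame_rate=200.0):
    x = np.asarray(x, dtype=float)
    return KinematicSeries(
        time_s=np.arange(x.size) / frame_rate, gape_cm=np.zeros_like(x),
        larynx_cm=x, axis="antero_posterior", view="dorsal",
        frame_rate_hz=frame_rate,
    )


class TestExtractEvents:
    def test_flat_signal_has_no_events(self):
        assert kin.extract_events(_series(np.full(500, 2.0)), "breathing") == []

    def test_single_half_sine_measured_exactly(self):
        fs, dur = 200.0, 0.9
        n_ev = int(dur * fs)
        x = np.full(1000, 3.0)
        x[400:400 + n_ev] += 0.5 * np.sin(np.pi * np.arange(n_ev) / n_ev)
        events = kin.extract_events(_series(x), "vocalization")
        assert len(events) == 1
        assert events[0].total_movement_cm == pytest.approx(0.5, abs=1e-3)
        assert events[0].cycle_duration_s == pytest.approx(dur, abs=1 / fs)

    def test_generator_event_count_recovered(self):
        params = synth.kinematic_defaults("vocalization", "dorsal",
                                          n_events=5, seed=3, noise_cm=0.01)
        res = synth.synth_kinematic_sequence(params)
        series = kin.compute_series(kin.smooth_track(res.track))
        events = kin.extract_events(series, "vocalization")
        assert len(events) == 5

    def test_translation_invariance(self):
        fs = 200.0
        n_ev = int(0.8 * fs)
        x = np.zeros(1000)
        x[300:300 + n_ev] += 0.4 * np.sin(np.pi * np.arange(n_ev) / n_ev)
        a = kin.extract_events(_series(x + 2.0), "breathing")
        b = kin.extract_events(_series(x + 7.5), "breathing")
        assert len(a) == len(b) == 1
        assert a[0].total_movement_cm == pytest.approx(b[0].total_movement_cm)
        assert a[0].cycle_duration_s == pytest.approx(b[0].cycle_duration_s)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            kin.extract_events(_series(np.ones(2)), "breathing")


def _events(disp_breath, disp_voc):
    evs = []
    for v in disp_breath:
        evs.append(kin.MovementEvent("breathing", "antero_posterior",
                                     v, 1.0, 0.0))
    for v in disp_voc:
        evs.append(kin.MovementEvent("vocalization", "antero_posterior",
                                     v, 1.0, 0.0))
    return evs


class TestCompareBehaviors:
    def test_identical_groups_give_zero_f(self):
        evs = _events([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        res = kin.compare_behaviors(evs, "displacement")
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_closed_form_anova_on_small_fixture(self):
        breath = [0.05, 0.07, 0.06, 0.08]
        voc = [0.40, 0.55, 0.62, 0.48]
        res = kin.compare_behaviors(_events(breath, voc), "displacement")
        # textbook one-way ANOVA on the log10 data, computed by hand
        g1, g2 = np.log10(breath), np.log10(voc)
        grand = np.concatenate([g1, g2]).mean()
        ss_between = 4 * (g1.mean() - grand) ** 2 + 4 * (g2.mean() - grand) ** 2
        ss_within = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        f_oracle = (ss_between / 1) / (ss_within / 6)
        assert res.F == pytest.approx(f_oracle, rel=1e-10)
        assert res.df == (1, 6)

    def test_scale_invariance_of_f_on_log_data(self):
        evs = _events([0.05, 0.07, 0.06], [0.4, 0.5, 0.6])
        scaled = _events([0.5, 0.7, 0.6], [4.0, 5.0, 6.0])
        f1 = kin.compare_behaviors(evs, "displacement").F
        f2 = kin.compare_behaviors(scaled, "displacement").F
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_calibrated_populations_separate(self):
        rng = np.random.default_rng(0)
        evs = []
        for behavior in ("breathing", "vocalization"):
            params = synth.kinematic_defaults(behavior, "dorsal",
                                              n_events=50, noise_cm=0.01,
                                              seed=int(rng.integers(2**31)))
            res = synth.synth_kinematic_sequence(params)
            series = kin.compute_series(kin.smooth_track(res.track))
            evs += kin.extract_events(series, behavior)
        out = kin.compare_behaviors(evs, "displacement")
        assert out.group_means["vocalization"] > out.group_means["breathing"]
        assert out.p < 0.05

    def test_missing_behavior_rejected(self):
        evs = _events([0.1, 0.2], [])
        with pytest.raises(ValueError):
            kin.compare_behaviors(evs, "displacement")


class TestJawLarynxCoupling:
    def _series(self, gape, larynx):
        gape = np.asarray(gape, dtype=float)
        return KinematicSeries(
            time_s=np.arange(gape.size) / 200.0, gape_cm=gape,
            larynx_cm=np.asarray(larynx, dtype=float),
            axis="antero_posterior", view="dorsal", frame_rate_hz=200.0,
        )

    def test_exact_linear_relation_gives_r2_one(self):
        g = np.linspace(0, 1, 100)
        assert kin.jaw_larynx_coupling(self._series(g, 2 * g + 1)) == \
            pytest.approx(1.0)

    def test_quadrature_sinusoids_uncorrelated(self):
        t = np.linspace(0, 2 * np.pi * 5, 1000, endpoint=False)
        r2 = kin.jaw_larynx_coupling(self._series(np.sin(t), np.cos(t)))
        assert r2 == pytest.approx(0.0, abs=1e-3)

    def test_equals_squared_pearson_correlation(self):
        rng = np.random.default_rng(12)
        g, l = rng.normal(size=200), rng.normal(size=200)
        r2 = kin.jaw_larynx_coupling(self._series(g, l))
        assert r2 == pytest.approx(np.corrcoef(g, l)[0, 1] ** 2, rel=1e-10)

    def test_zero_variance_gape_flagged_nan(self):
        r2 = kin.jaw_larynx_coupling(self._series(np.ones(50),
                                                  np.arange(50.0)))
        assert np.isnan(r2)
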