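"""Signal-conditioning chain: ectopic repair, resampling, normalization,
filtering, artifact masking."""

import numpy as np
import pytest

from vocrisk.preprocessing import (
    BeatSeries,
    ProcessingError,
    UniformSeries,
    beats_to_uniform,
    effective_sleep_duration,
    interpolate_ectopic,
    lowpass,
    mask_artifacts,
    normalize_ppga,
    preprocess_night,
)


def make_beats(rri, ppga=None):
    rri = np.asarray(rri, dtype=float)
    t = np.concatenate([[0.0], np.cumsum(rri[:-1])])
    if ppga is None:
        ppga = np.ones_like(rri)
    return BeatSeries(beat_times=t, rri=rri, ppga=np.asarray(ppga, dtype=float))


class TestInterpolateEctopic:
    def test_constant_series_unchanged(self):
        beats = make_beats(np.full(100, 0.8))
        out = interpolate_ectopic(beats)
        np.testing.assert_array_equal(out.rri, beats.rri)

    def test_single_spike_replaced_others_untouched(self, rng):
        rri = 0.8 + rng.normal(0, 0.02, 1000)
        mu, sd = rri.mean(), rri.std()
        rri[500] = mu + 5 * sd
        beats = make_beats(rri)
        # independent oracle: direct z-score scan on the raw series
        z = np.abs(beats.rri - beats.rri.mean()) / beats.rri.std()
        expected_ectopic = np.flatnonzero(z > 3.5)
        out = interpolate_ectopic(beats)
        changed = np.flatnonzero(out.rri != beats.rri)
        np.testing.assert_array_equal(changed, expected_ectopic)
        # replacement interpolates between non-ectopic neighbours
        assert abs(out.rri[500] - (rri[499] + rri[501]) / 2) < 0.05

    def test_infinite_threshold_is_identity(self, rng):
        beats = make_beats(0.8 + rng.normal(0, 0.1, 50))
        out = interpolate_ectopic(beats, z=np.inf)
        np.testing.assert_array_equal(out.rri, beats.rri)

    def test_inputs_not_modified(self, rng):
        rri = 0.8 + rng.normal(0, 0.01, 200)
        rri[10] = 3.0
        beats = make_beats(rri)
        before = beats.rri.copy()
        interpolate_ectopic(beats)
        np.testing.assert_array_equal(beats.rri, before)

    def test_too_few_beats(self):
        with pytest.raises(ProcessingError):
            interpolate_ectopic(make_beats([0.8, 0.8]))


class TestBeatsToUniform:
    def test_constant_rri_resamples_to_constant(self):
        beats = make_beats(np.full(200, 1.0))
        out = beats_to_uniform(beats, "RRI")
        np.testing.assert_allclose(out.values, 1.0)
        assert out.rate == 2.0

    def test_interval_average_of_alternating_hold(self):
        """Held PPGa alternating 1/2 with equal time -> window average 1.5."""
        n = 400
        rri = np.full(n, 0.25)
        ppga = np.tile([1.0, 2.0], n // 2)
        beats = make_beats(rri, ppga)
        out = beats_to_uniform(beats, "PPGa")
        np.testing.assert_allclose(out.values[1:-1], 1.5)

    def test_duration_within_one_sample_of_recording(self, rng):
        rri = 0.8 + rng.normal(0, 0.05, 500)
        beats = make_beats(rri)
        out = beats_to_uniform(beats, "PPGa")
        recording = beats.beat_times[-1] - beats.beat_times[0]
        assert abs(len(out) / out.rate - recording) <= 1 / out.rate

    def test_empty_input_errors(self):
        with pytest.raises(ProcessingError):
            beats_to_uniform(make_beats([0.8]), "RRI")


class TestNormalizePPGa:
    def test_divides_by_95th_percentile(self, rng):
        values = rng.uniform(0.5, 2.0, 500)
        series = UniformSeries(values=values, channel="PPGa")
        out = normalize_ppga(series)
        ref = np.percentile(values, 95)
        np.testing.assert_allclose(out.values, values / ref)
        # idempotent reference: post-normalization 95th percentile is 1
        assert np.percentile(out.values, 95) == pytest.approx(1.0)

    def test_masked_samples_excluded_from_percentile(self, rng):
        values = rng.uniform(0.5, 1.0, 200)
        values[:50] = 50.0  # artifact-corrupted stretch
        mask = np.ones(200, dtype=bool)
        mask[:50] = False
        out = normalize_ppga(UniformSeries(values=values, mask=mask, channel="PPGa"))
        ref = np.percentile(values[mask], 95)  # oracle: unmasked subset
        np.testing.assert_allclose(out.values, values / ref)

    def test_nonpositive_reference_errors(self):
        series = UniformSeries(values=np.zeros(100), channel="PPGa")
        with pytest.raises(ProcessingError):
            normalize_ppga(series)


class TestLowpass:
    def _sine(self, freq, n=2400, rate=2.0):
        t = np.arange(n) / rate
        return UniformSeries(values=np.sin(2 * np.pi * freq * t), channel="PPGa")

    def test_dc_gain_is_one(self):
        series = UniformSeries(values=np.full(1000, 3.7), channel="PPGa")
        out = lowpass(series)
        np.testing.assert_allclose(out.values, 3.7, atol=1e-9)

    def test_respiratory_band_attenuated(self):
        out = lowpass(self._sine(0.25))
        mid = out.values[400:-400]
        assert np.abs(mid).max() < 0.5

    def test_slow_dynamics_preserved(self):
        out = lowpass(self._sine(0.01))
        mid = out.values[400:-400]
        assert np.abs(mid).max() > 0.95

    def test_stopband_attenuation_exceeds_20db(self):
        out = lowpass(self._sine(0.3))
        mid = out.values[400:-400]
        assert np.abs(mid).max() < 10 ** (-20 / 20)

    def test_short_series_errors(self):
        with pytest.raises(ProcessingError):
            lowpass(UniformSeries(values=np.ones(5), channel="PPGa"))


class TestMaskArtifacts:
    def test_empty_interval_list_is_identity(self, rng):
        series = UniformSeries(values=rng.random(100))
        out = mask_artifacts(series, [])
        assert out.mask.all()

    def test_masked_time_reduces_effective_sleep_duration(self):
        n = 7200  # one hour at 2 Hz
        series = UniformSeries(values=np.ones(n))
        out = mask_artifacts(series, [(0.0, 360.0)])  # 10% of the hour
        assert effective_sleep_duration(out) == pytest.approx(0.9)

    def test_inputs_not_modified(self):
        series = UniformSeries(values=np.ones(100))
        mask_artifacts(series, [(0.0, 10.0)])
        assert series.mask.all()


class TestFullChain:
    def test_event_depth_preserved_through_chain(self):
        """The chain keeps a plateau event's fractional depth within 2%."""
        from vocrisk.synthetic_data import SubjectProfile, generate_subject_signals

        profile = SubjectProfile(
            subject_id="S", mean_rri=0.8, baseline_ppga=1.0, sleep_hours=1.0,
            events=((1200.0, 80.0, 30.0),), noise_sd=0.0, resp_amplitude=0.05,
            hrv_sd=0.0,
        )
        beats = generate_subject_signals(profile, seed=0)
        ppga, _ = preprocess_night(beats)
        t = ppga.times
        base = ppga.values[(t > 1100) & (t < 1190)].mean()
        trough = ppga.values[(t > 1220) & (t < 1255)].min()
        assert 1 - trough / base == pytest.approx(0.30, abs=0.02)
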