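"""Preprocessing chain: resampling, referencing, filtering, masking, segmentation, STFT."""

import numpy as np
import pytest

from eegage.preprocess import (
    PreprocessConfig,
    artifact_mask,
    bandpass_filter,
    common_average_reference,
    expected_stft_shape,
    preprocess_recording,
    resample_recording,
    retain_segments,
    segment_recording,
    stft_graph,
)
from eegage.recording import Segment

from conftest import make_recording


def sine_recording(freq_hz, rate, seconds, n_chan=2, amplitude=1.0):
    t = np.arange(int(seconds * rate)) / rate
    wave = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return make_recording(np.tile(wave, (n_chan, 1)), rate=rate)


class TestResample:
    def test_downsample_preserves_duration(self, rng):
        rec = make_recording(rng.normal(size=(3, 5000)), rate=500.0)
        out = resample_recording(rec, 200.0)
        assert out.rate == 200.0
        assert out.n_samples == 2000

    def test_identity_when_rate_matches(self, random_recording):
        out = resample_recording(random_recording, 200.0)
        assert out is random_recording

    def test_dominant_frequency_survives(self):
        rec = sine_recording(10.0, rate=500.0, seconds=10.0)
        out = resample_recording(rec, 200.0)
        spec = np.abs(np.fft.rfft(out.data[0]))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 200.0)
        assert abs(freqs[np.argmax(spec)] - 10.0) < 0.2

    def test_upsampling_refused(self, random_recording):
        with pytest.raises(ValueError, match="upsampling"):
            resample_recording(random_recording, 500.0)


class TestCommonAverageReference:
    def test_two_channel_example(self):
        rec = make_recording(np.array([[1.0], [3.0]]))
        out = common_average_reference(rec)
        assert np.allclose(out.data[:, 0], [-1.0, 1.0])

    def test_zero_mean_input_unchanged(self, rng):
        data = rng.normal(size=(4, 100))
        data -= data.mean(axis=0, keepdims=True)
        out = common_average_reference(make_recording(data))
        assert np.allclose(out.data, data)

    def test_channel_means_vanish(self, random_recording):
        out = common_average_reference(random_recording)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_single_channel_error(self, rng):
        with pytest.raises(ValueError):
            common_average_reference(make_recording(rng.normal(size=(1, 100))))


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        rec = sine_recording(10.0, 200.0, 60.0)
        out = bandpass_filter(rec, 1.0, 70.0)
        mid = out.data[0, 2000:-2000]
        assert abs(mid.max() - 1.0) < 0.05

    def test_dc_removed(self, rng):
        rec = make_recording(rng.normal(size=(2, 4000)) + 100.0)
        out = bandpass_filter(rec, 1.0, 70.0)
        assert abs(out.data.mean()) < 1.0

    @pytest.mark.parametrize("freq", [0.1, 90.0])
    def test_stopband_attenuation(self, freq):
        rec = sine_recording(freq, 200.0, 60.0)
        out = bandpass_filter(rec, 1.0, 70.0)
        in_rms = np.sqrt((rec.data[0] ** 2).mean())
        out_rms = np.sqrt((out.data[0, 2000:-2000] ** 2).mean())
        assert out_rms / in_rms < 0.1  # >= 20 dB

    def test_cutoff_above_nyquist_refused(self, random_recording):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(random_recording, 1.0, 110.0)


class TestArtifactMask:
    def test_all_zero_recording(self):
        rec = make_recording(np.zeros((3, 50)))
        assert not artifact_mask(rec, 200.0).any()

    def test_single_excursion_flagged(self):
        data = np.zeros((3, 20))
        data[1, 7] = 250.0
        mask = artifact_mask(make_recording(data), 200.0)
        assert mask[7] and mask.sum() == 1

    def test_matches_bruteforce_scan(self, random_recording):
        mask = artifact_mask(random_recording, 100.0)
        brute = np.array(
            [
                max(abs(random_recording.data[c, t]) for c in range(19)) > 100.0
                for t in range(random_recording.n_samples)
            ]
        )
        assert np.array_equal(mask, brute)

    def test_negative_threshold_refused(self, random_recording):
        with pytest.raises(ValueError):
            artifact_mask(random_recording, -1.0)


class TestSegmentation:
    @pytest.mark.parametrize(
        "minutes,expected", [(20, 31), (5, 1), (4, 0)]
    )
    def test_segment_counts(self, rng, minutes, expected):
        rec = make_recording(rng.normal(size=(2, int(minutes * 60 * 200))))
        segs = segment_recording(rec, 300.0, 30.0)
        assert len(segs) == expected
        if segs:
            assert segs[0].start_seconds == 0.0
            assert np.allclose(np.diff([s.start_seconds for s in segs]), 30.0)

    def test_artifact_fraction_propagates(self, rng):
        rec = make_recording(rng.normal(size=(2, 2000)))
        mask = np.zeros(2000, dtype=bool)
        mask[:500] = True
        segs = segment_recording(rec, 5.0, 5.0, mask)
        assert segs[0].artifact_fraction == 0.5
        assert segs[1].artifact_fraction == 0.0

    def test_retention_strictly_below_cutoff(self, rng):
        def seg(frac):
            return Segment(
                data=np.zeros((2, 10)), rate=200.0, start_seconds=0.0, artifact_fraction=frac
            )

        segs = [seg(0.0), seg(0.29), seg(0.30), seg(0.9)]
        kept = retain_segments(segs, 0.30)
        assert [s.artifact_fraction for s in kept] == [0.0, 0.29]

    def test_retention_handles_empty_and_clean(self):
        assert retain_segments([], 0.3) == []
        clean = [
            Segment(np.zeros((1, 4)), 200.0, float(i), 0.0) for i in range(31)
        ]
        assert len(retain_segments(clean, 0.3)) == 31


class TestStft:
    def test_five_minute_segment_dimensions(self, rng):
        seg = Segment(
            data=rng.normal(size=(19, 60000)), rate=200.0, start_seconds=0.0,
            artifact_fraction=0.0,
        )
        graph = stft_graph(seg)
        assert graph.shape == (19, 157, 149)
        assert graph.freqs_hz[0] == 1.0 and graph.freqs_hz[-1] == 40.0
        assert expected_stft_shape() == (157, 149)

    def test_pure_tone_lands_in_its_bin(self):
        t = np.arange(12000) / 200.0
        seg = Segment(
            data=np.sin(2 * np.pi * 10.0 * t)[None, :], rate=200.0, start_seconds=0.0,
            artifact_fraction=0.0,
        )
        graph = stft_graph(seg, scale="magnitude")
        peak_bin = graph.values[0].mean(axis=1).argmax()
        assert peak_bin == 36  # (10 - 1) / 0.25
        assert graph.freqs_hz[peak_bin] == 10.0

    def test_zero_segment_zero_magnitude(self):
        seg = Segment(np.zeros((2, 2000)), 200.0, 0.0, 0.0)
        graph = stft_graph(seg, scale="magnitude")
        assert np.all(graph.values == 0.0)
        assert np.all(graph.values >= 0.0)

    def test_window_longer_than_segment_refused(self):
        seg = Segment(np.zeros((1, 100)), 200.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            stft_graph(seg, window_seconds=4.0)


class TestFullChain:
    def test_pipeline_is_deterministic(self, rng):
        data = rng.normal(0.0, 30.0, size=(19, 72000))
        cfg = PreprocessConfig(window_seconds=60.0, step_seconds=30.0)
        rec = make_recording(data)
        a = preprocess_recording(rec, cfg)
        b = preprocess_recording(make_recording(data.copy()), cfg)
        assert len(a.graphs) == len(b.graphs) == 11
        for ga, gb in zip(a.graphs, b.graphs):
            assert np.array_equal(ga.values, gb.values)

    def test_manifest_rows_cover_all_segments(self, rng):
        data = rng.normal(0.0, 30.0, size=(19, 72000))
        # poison 30 s with a large in-band oscillation (survives the band-pass)
        t = np.arange(6000) / 200.0
        data[0, 10000:16000] = 500.0 * np.sin(2 * np.pi * 5.0 * t)
        cfg = PreprocessConfig(window_seconds=60.0, step_seconds=30.0)
        res = preprocess_recording(make_recording(data), cfg)
        assert len(res.manifest_rows) == 11
        retained = [r for r in res.manifest_rows if r["retained"]]
        assert len(retained) == len(res.graphs) < 11
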