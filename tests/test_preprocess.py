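"""Signal normalisation, band-pass filtering and the Morlet CWT scalograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from merdbs.cohort import ConfigurationError, MerSegment
from merdbs.preprocess import (
    DegenerateSignalError,
    MorletParams,
    PreprocessConfig,
    band_frequencies,
    bandpass,
    cwt,
    cwt_complex,
    frequency_to_scale,
    make_band_scalograms,
    morlet,
    normalize_signal,
    scale_to_frequency,
    scales_for_band,
)


def tone_segment(freq, fs=4000, duration=1.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(fs * duration)) / fs
    return MerSegment(
        samples=(amplitude * np.sin(2 * np.pi * freq * t + phase)).astype(np.float32),
        sampling_rate_hz=fs,
        patient_id="tone",
    )


def cwt_direct(x, fs, scales, omega0):
    """Independent oracle: the discretised CWT integral, summed directly."""
    x = np.asarray(x, dtype=float)
    dt = 1.0 / fs
    t = np.arange(len(x)) * dt
    out = np.empty((len(scales), len(x)), dtype=complex)
    for j, a in enumerate(scales):
        for k in range(len(x)):
            arg = (t - t[k]) / a
            out[j, k] = np.sum(x * np.conj(morlet(arg, omega0))) * dt / np.sqrt(a)
    return out


class TestNormalizeSignal:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([0.0, 5.0, 10.0], [0.0, 0.5, 1.0]),
            ([-3.0, -1.0, 1.0], [0.0, 0.5, 1.0]),
        ],
    )
    def test_affine_minmax(self, x, expected):
        np.testing.assert_allclose(normalize_signal(np.array(x)), expected)

    def test_already_unit_range_unchanged(self):
        x = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(normalize_signal(x), x)

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            normalize_signal(np.full(10, 3.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=50).filter(
            lambda v: max(v) > min(v)
        )
    )
    def test_range_and_idempotence(self, values):
        y = normalize_signal(np.array(values))
        assert y.min() == 0.0 and y.max() == 1.0
        np.testing.assert_allclose(normalize_signal(y), y, atol=1e-12)


class TestBandpass:
    def test_passband_tone_preserved(self):
        seg = tone_segment(200.0)
        out = bandpass(seg, 50, 500)
        ratio = np.std(out.samples[200:-200]) / np.std(seg.samples[200:-200])
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_tone_removed(self):
        seg = tone_segment(10.0)
        out = bandpass(seg, 50, 500)
        assert np.std(out.samples) < 0.05 * np.std(seg.samples)

    def test_attenuation_one_octave_beyond_edge(self):
        seg = tone_segment(25.0)  # one octave below the 50 Hz edge
        out = bandpass(seg, 50, 500)
        attenuation_db = 20 * np.log10(np.std(out.samples) / np.std(seg.samples))
        assert attenuation_db <= -40

    def test_zero_signal_maps_to_zero(self):
        seg = MerSegment(samples=np.zeros(1000, dtype=np.float32), sampling_rate_hz=4000, patient_id="z")
        np.testing.assert_allclose(bandpass(seg, 50, 500).samples, 0.0, atol=1e-12)

    def test_invalid_edges_rejected(self):
        seg = tone_segment(100.0)
        with pytest.raises(ConfigurationError):
            bandpass(seg, 500, 50)
        with pytest.raises(ConfigurationError):
            bandpass(seg, 50, 3000)  # above Nyquist at fs=4000


class TestMorlet:
    def test_value_at_zero(self):
        assert morlet(0.0) == pytest.approx(np.pi ** (-0.25))
        assert morlet(0.0).imag == pytest.approx(0.0)

    def test_envelope_ratio_at_six(self):
        assert abs(morlet(6.0)) / abs(morlet(0.0)) == pytest.approx(np.exp(-18.0), rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-20, 20, allow_nan=False))
    def test_envelope_symmetry(self, t):
        assert abs(morlet(-t)) == pytest.approx(abs(morlet(t)), rel=1e-10)


class TestCwt:
    def test_zero_signal_zero_scalogram(self):
        seg = MerSegment(samples=np.zeros(512, dtype=np.float32), sampling_rate_hz=1000, patient_id="z")
        params = MorletParams(scale_grid=frequency_to_scale([200, 100, 50]))
        assert np.allclose(cwt(seg, params).values, 0.0)

    def test_linearity_in_complex_domain(self, rng):
        x1 = rng.standard_normal(512)
        x2 = rng.standard_normal(512)
        scales = frequency_to_scale([200.0, 100.0, 50.0])
        both = cwt_complex(x1 + x2, 1000, scales)
        np.testing.assert_allclose(
            both, cwt_complex(x1, 1000, scales) + cwt_complex(x2, 1000, scales), atol=1e-9
        )

    def test_matches_direct_integral_oracle(self, rng):
        """Fast convolution equals the direct discretised integral."""
        fs = 1000.0
        x = np.sin(2 * np.pi * 80 * np.arange(512) / fs) + 0.3 * rng.standard_normal(512)
        scales = scales_for_band("50-500", MorletParams(voices_per_octave=4))[:6]
        fast = cwt_complex(x, fs, scales)
        direct = cwt_direct(x, fs, scales, 6.0)
        rel = np.abs(fast - direct).max() / np.abs(direct).max()
        assert rel < 1e-6

    def test_tone_peak_row_maps_to_tone_frequency(self):
        seg = tone_segment(100.0, fs=2000)
        params = MorletParams(voices_per_octave=16)
        scal = cwt(seg, params, band="50-500")
        peak_freq = scal.freqs_hz[scal.values.mean(axis=1).argmax()]
        assert peak_freq == pytest.approx(100.0, rel=0.05)

    def test_empty_or_invalid_scale_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            cwt_complex(np.zeros(64), 1000, [])
        with pytest.raises(ConfigurationError):
            cwt_complex(np.zeros(64), 1000, frequency_to_scale([900.0]))  # above Nyquist

    def test_energy_monotone_in_tone_amplitude(self):
        peaks = []
        for amp in (0.5, 1.0, 2.0):
            seg = tone_segment(150.0, fs=2000, amplitude=amp)
            scal = cwt(seg, MorletParams(), band="50-500")
            peaks.append(scal.values.max())
        assert peaks[0] < peaks[1] < peaks[2]


class TestBandScalograms:
    def test_in_band_tone_concentrates_near_tone(self):
        seg = tone_segment(200.0, fs=4000)
        scal = make_band_scalograms(seg, "50-500", PreprocessConfig(image_size=(64, 64)))
        assert scal.values.shape == (64, 64)
        assert scal.values.min() == 0.0 and scal.values.max() == 1.0
        peak_freq = scal.freqs_hz[scal.values.mean(axis=1).argmax()]
        assert peak_freq == pytest.approx(200.0, rel=0.15)

    def test_out_of_band_tone_nearly_silent(self):
        # zero-mean input isolates the band-selection question from the DC
        # offset that min-max signal normalisation would introduce
        seg = tone_segment(200.0, fs=4000)
        cfg = PreprocessConfig(image_size=(32, 32), image_norm=False, signal_norm=False)
        in_band = make_band_scalograms(seg, "50-500", cfg)
        out_band = make_band_scalograms(seg, "1-50", cfg)
        # residual out-of-band energy stems from the retained zero-padding
        # edge effects (the 1-50 Hz kernels outlast the 1 s signal)
        assert out_band.values.max() < 0.1 * in_band.values.max()

    @pytest.mark.parametrize("fs, duration", [(4000, 0.5), (8000, 0.25)])
    def test_output_size_independent_of_input_length(self, fs, duration):
        seg = tone_segment(100.0, fs=fs, duration=duration)
        scal = make_band_scalograms(seg, "50-500", PreprocessConfig(image_size=(48, 40)))
        assert scal.values.shape == (48, 40)

    def test_rows_lie_inside_band(self):
        freqs = band_frequencies("50-500", voices_per_octave=8)
        assert freqs.max() <= 500.0 * (1 + 1e-9) and freqs.min() >= 50.0 * (1 - 1e-9)
        seg = tone_segment(100.0, fs=4000)
        scal = make_band_scalograms(seg, "50-500")
        assert scal.freqs_hz.max() <= 500.0 and scal.freqs_hz.min() >= 50.0

    def test_band_above_nyquist_rejected(self):
        seg = tone_segment(100.0, fs=4000)
        with pytest.raises(ConfigurationError):
            make_band_scalograms(seg, "500-5000")

    def test_bandpass_first_toggle_runs(self):
        seg = tone_segment(200.0, fs=4000)
        scal = make_band_scalograms(seg, "50-500", PreprocessConfig(bandpass_first=True))
        assert scal.values.shape == (64, 64)


class TestScaleFrequencyMap:
    def test_inverse_proportionality(self):
        scales = frequency_to_scale([50.0, 100.0, 200.0])
        np.testing.assert_allclose(scale_to_frequency(scales), [50.0, 100.0, 200.0])
        assert scales[0] > scales[1] > scales[2]  # lower frequency -> larger scale

    def test_peak_recovery_across_band_tones(self):
        """Tones across each representable band are recovered within 5 %."""
        params = MorletParams(voices_per_octave=16)
        for band, fs in [("1-50", 400), ("50-500", 4000)]:
            lo, hi = (float(v) for v in band.split("-"))
            for f0 in np.geomspace(lo * 1.5, hi / 1.5, 5):
                seg = tone_segment(f0, fs=fs, duration=max(1.0, 8.0 / f0))
                scal = cwt(seg, params, band=band)
                peak = scal.freqs_hz[scal.values.mean(axis=1).argmax()]
                assert peak == pytest.approx(f0, rel=0.05), (band, f0)
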