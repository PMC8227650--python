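"""VFCDM: demodulation, frequency tracking, band selectivity, reconstruction."""

import numpy as np
import pytest
from scipy.signal import periodogram

from edapain.records import UniformSeries, ValidationError
from edapain.vfcdm import (
    EDGE_SECONDS,
    band_centers,
    fixed_demodulate,
    instantaneous_frequency,
    variable_demodulate,
    vfcdm_decompose,
)

EDGE = int(EDGE_SECONDS * 2)  # samples to drop at each end


def _tone(f, dur=300.0, rate=2.0, phase=0.0):
    t = np.arange(0, dur, 1 / rate)
    return UniformSeries(values=np.cos(2 * np.pi * f * t + phase), rate=rate)


class TestFixedDemodulate:
    def test_band_centers_layout(self):
        c = band_centers()
        assert c.size == 12
        np.testing.assert_allclose(c, 0.04 + 0.08 * np.arange(12))

    def test_pure_tone_amplitude_near_one(self):
        env = fixed_demodulate(_tone(0.12), 0.12)
        interior = env.amplitude[EDGE:-EDGE]
        np.testing.assert_allclose(interior, 1.0, rtol=0.02)

    def test_zero_input_zero_amplitude(self):
        s = UniformSeries(values=np.zeros(600), rate=2.0)
        assert fixed_demodulate(s, 0.12).amplitude.max() == 0.0

    def test_stopband_rejection(self):
        env = fixed_demodulate(_tone(0.12 + 3 * 0.08), 0.12)
        assert env.amplitude[EDGE:-EDGE].max() < 0.05

    def test_f0_beyond_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            fixed_demodulate(_tone(0.12), 1.5)


class TestInstantaneousFrequency:
    def test_tone_at_center_tracks_center(self):
        env = fixed_demodulate(_tone(0.12), 0.12)
        f = instantaneous_frequency(env)
        np.testing.assert_allclose(f[EDGE:-EDGE], 0.12, atol=1e-3)

    def test_detuned_tone_tracked(self):
        env = fixed_demodulate(_tone(0.15), 0.12)
        f = instantaneous_frequency(env)
        # the track smoothing filter spans 16 s, so allow a wider edge margin
        np.testing.assert_allclose(f[2 * EDGE : -2 * EDGE], 0.15, atol=2e-3)

    def test_zero_envelope_falls_back_to_center(self):
        s = UniformSeries(values=np.zeros(600), rate=2.0)
        f = instantaneous_frequency(fixed_demodulate(s, 0.12))
        np.testing.assert_array_equal(f, 0.12)


class TestVariableDemodulate:
    def test_chirp_reconstructed(self):
        rate = 2.0
        t = np.arange(0, 300, 1 / rate)
        inst_f = 0.12 + 0.02 * np.sin(2 * np.pi * t / 150)
        phase = 2 * np.pi * np.cumsum(inst_f) / rate
        s = UniformSeries(values=np.cos(phase), rate=rate)
        env = fixed_demodulate(s, 0.12)
        track = instantaneous_frequency(env)
        comp = variable_demodulate(s, track)
        sl = slice(EDGE, -EDGE)
        r = np.corrcoef(comp[sl], s.values[sl])[0, 1]
        assert r > 0.95

    def test_zero_input_zero_component(self):
        s = UniformSeries(values=np.zeros(600), rate=2.0)
        comp = variable_demodulate(s, np.full(600, 0.12))
        np.testing.assert_array_equal(comp, 0.0)

    def test_constant_track_equals_fixed_demodulation(self):
        s = _tone(0.13)
        env = fixed_demodulate(s, 0.12)
        t = np.arange(len(s)) / s.rate
        fixed_comp = env.amplitude * np.cos(2 * np.pi * 0.12 * t + env.phase)
        var_comp = variable_demodulate(s, np.full(len(s), 0.12))
        np.testing.assert_allclose(var_comp, fixed_comp, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            variable_demodulate(_tone(0.12), np.full(10, 0.12))


class TestDecompose:
    def test_tone_lands_in_band_two(self, tone_series):
        d = vfcdm_decompose(tone_series)
        var = d.components.var(axis=1)
        assert var[1] / var.sum() >= 0.90

    def test_zero_input_all_zero(self):
        s = UniformSeries(values=np.zeros(600), rate=2.0)
        assert np.abs(vfcdm_decompose(s).components).max() == 0.0

    def test_broadband_reconstruction(self, broadband_series):
        d = vfcdm_decompose(broadband_series)
        sl = slice(EDGE, -EDGE)
        err = d.reconstruct()[sl] - broadband_series.values[sl]
        rel_rmse = np.sqrt(np.mean(err**2)) / broadband_series.values[sl].std()
        assert rel_rmse < 0.05

    def test_linearity(self, broadband_series):
        d1 = vfcdm_decompose(broadband_series)
        s3 = UniformSeries(values=3.0 * broadband_series.values, rate=2.0)
        d3 = vfcdm_decompose(s3)
        np.testing.assert_allclose(d3.components, 3.0 * d1.components, atol=1e-8)

    def test_band_energy_concentration(self, broadband_series):
        d = vfcdm_decompose(broadband_series)
        for k in range(1, 11):  # interior bands
            f, pxx = periodogram(d.components[k], fs=2.0)
            c = d.center_frequencies[k]
            in_band = pxx[(f >= c - 0.06) & (f <= c + 0.06)].sum()
            assert in_band / pxx.sum() >= 0.80, f"band {k + 1}"

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            vfcdm_decompose(UniformSeries(values=np.zeros(40), rate=2.0))
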