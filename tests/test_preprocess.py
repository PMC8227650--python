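"""Preprocessing chain: spline resampling, median, decimation, high-pass."""

import numpy as np
import pytest

from edapain.preprocess import (
    downsample_to_2hz,
    highpass_001,
    median_filter_1s,
    preprocess_eda,
    resample_cubic_spline,
)
from edapain.records import RawEDARecord, UniformSeries, ValidationError


def _record(t, v, sid="s"):
    return RawEDARecord(subject_id=sid, timestamps=t, conductance=v)


class TestResample:
    def test_reproduces_values_at_knots_of_uniform_input(self):
        t = np.arange(0, 10, 0.25)
        v = np.sin(t) + 2.0
        out = resample_cubic_spline(_record(t, v), 4.0)
        np.testing.assert_allclose(out.values, v, atol=1e-9)

    def test_constant_input_stays_constant(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 30, 200))
        t[0], t[-1] = 0.0, 30.0
        out = resample_cubic_spline(_record(t, np.full(200, 1.5)), 4.0)
        np.testing.assert_allclose(out.values, 1.5, atol=1e-12)

    def test_slow_sinusoid_matches_analytic(self):
        rng = np.random.default_rng(1)
        t = np.cumsum(rng.uniform(0.005, 0.012, 8000))
        v = np.sin(2 * np.pi * 0.05 * t) + 2.0
        out = resample_cubic_spline(_record(t, v), 4.0)
        expected = np.sin(2 * np.pi * 0.05 * out.times) + 2.0
        assert np.abs(out.values - expected).max() < 1e-6

    def test_too_few_samples_raise(self):
        with pytest.raises(ValidationError):
            resample_cubic_spline(_record(np.array([0.0, 1.0, 2.0]), np.ones(3)), 4.0)

    def test_grid_anchored_at_first_timestamp(self):
        t = np.linspace(5.0, 15.0, 100)
        out = resample_cubic_spline(_record(t, np.ones(100)), 4.0)
        assert out.start_time == pytest.approx(5.0)
        assert out.times[-1] <= 15.0 + 1e-12


class TestMedian:
    def test_constant_unchanged(self):
        s = UniformSeries(values=np.full(40, 2.0), rate=4.0)
        np.testing.assert_array_equal(median_filter_1s(s).values, s.values)

    def test_single_spike_removed(self):
        v = np.full(40, 1.0)
        v[20] += 10.0
        out = median_filter_1s(UniformSeries(values=v, rate=4.0))
        np.testing.assert_allclose(out.values, 1.0)

    def test_monotone_ramp_interior_unchanged(self):
        v = np.arange(40.0)
        out = median_filter_1s(UniformSeries(values=v, rate=4.0))
        np.testing.assert_array_equal(out.values[2:-2], v[2:-2])


class TestDownsample:
    def test_length_halved(self):
        s = UniformSeries(values=np.arange(8.0), rate=4.0)
        out = downsample_to_2hz(s)
        assert len(out) == 4 and out.rate == 2.0

    def test_sinusoid_values_kept_exactly(self):
        t4 = np.arange(0, 100, 0.25)
        s = UniformSeries(values=np.sin(2 * np.pi * 0.1 * t4), rate=4.0)
        out = downsample_to_2hz(s)
        expected = np.sin(2 * np.pi * 0.1 * out.times)
        assert np.abs(out.values - expected).max() < 1e-6

    def test_wrong_rate_rejected(self):
        with pytest.raises(ValidationError):
            downsample_to_2hz(UniformSeries(values=np.zeros(10), rate=2.0))


class TestHighpass:
    def test_dc_rejection(self):
        s = UniformSeries(values=np.full(600, 2.0), rate=2.0)
        assert np.abs(highpass_001(s).values).max() < 1e-3

    def test_passband_amplitude_preserved(self):
        t = np.arange(0, 600, 0.5)
        s = UniformSeries(values=np.sin(2 * np.pi * 0.2 * t), rate=2.0)
        out = highpass_001(s).values[100:-100]
        amplitude = np.sqrt(2.0) * out.std()  # RMS estimate, robust to sample phase
        assert amplitude == pytest.approx(1.0, rel=0.02)

    def test_zero_in_zero_out(self):
        s = UniformSeries(values=np.zeros(100), rate=2.0)
        np.testing.assert_allclose(highpass_001(s).values, 0.0, atol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValidationError):
            highpass_001(UniformSeries(values=np.ones(5), rate=2.0))


class TestFullChain:
    def test_constant_record_near_zero(self):
        t = np.arange(0, 300, 1 / 32)
        out = preprocess_eda(_record(t, np.full(t.size, 2.0)))
        assert np.abs(out.values).max() < 1e-3

    def test_output_rate_and_length(self, subject):
        rec, _, _ = subject
        out = preprocess_eda(rec)
        assert out.rate == 2.0
        assert abs(len(out) - rec.duration * 2.0) <= 2

    def test_short_recording_rejected(self):
        t = np.arange(0, 30, 1 / 32)
        with pytest.raises(ValidationError):
            preprocess_eda(_record(t, np.full(t.size, 2.0)))

    def test_scaling_commutes_through_chain(self, subject):
        rec, _, _ = subject
        scaled = _record(rec.timestamps, rec.conductance * 3.0)
        out1 = preprocess_eda(rec)
        out3 = preprocess_eda(scaled)
        np.testing.assert_allclose(out3.values, 3.0 * out1.values, atol=1e-9)

    def test_stage_order_matters_on_spiky_input(self):
        # high-pass before the median no longer removes an isolated spike the
        # same way; the chain is therefore order-sensitive
        rng = np.random.default_rng(2)
        t = np.arange(0, 120, 1 / 32)
        v = 2.0 + 0.1 * np.sin(2 * np.pi * 0.1 * t)
        v[1000] += 5.0  # isolated artifact
        rec = _record(t, v)
        reference = preprocess_eda(rec)
        s4 = resample_cubic_spline(rec, 4.0)
        permuted = median_filter_1s(
            UniformSeries(values=highpass_001(downsample_to_2hz(s4)).values, rate=2.0)
        )
        n = min(len(reference), len(permuted))
        assert not np.allclose(reference.values[:n], permuted.values[:n], atol=1e-6)
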