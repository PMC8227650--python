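"""Four-step EDA preprocessing chain.

Raw wearable skin conductance is irregularly sampled (roughly 15-130 Hz
depending on the radio link).  All indices downstream operate on a uniform,
denoised, detrended 2 Hz series produced by:

1. cubic-spline resampling to 4 Hz,
2. a 1-s running median (5 samples at 4 Hz) to remove impulsive artifacts,
3. decimation to 2 Hz,
4. a 0.01 Hz high-pass to remove the tonic baseline / DC level.

In batch mode the high-pass is zero-phase (forward-backward Butterworth) so
SCR timing is preserved for segment analysis; streaming mode (see
:mod:`edapain.realtime`) uses the causal single-pass variant and a trailing
median instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, lfilter, lfilter_zi

from .records import PreprocessedEDA, RawEDARecord, UniformSeries, ValidationError

TARGET_RATE = 2.0  #: Hz of the final preprocessed series
INTERMEDIATE_RATE = 4.0  #: Hz of the spline/median stage
HIGHPASS_CUTOFF = 0.01  #: Hz
MEDIAN_WINDOW = 5  #: samples at 4 Hz (1.25 s; an odd window covering >= 1 s)


def resample_cubic_spline(record: RawEDARecord, target_rate: float = INTERMEDIATE_RATE) -> UniformSeries:
    """Natural cubic-spline interpolation onto a uniform grid.

    The grid is anchored at the first timestamp and never extends beyond the
    recorded span (no extrapolation).
    """
    if target_rate <= 0:
        raise ValidationError("target_rate must be positive")
    if len(record) < 4:
        raise ValidationError("need at least 4 samples for cubic-spline resampling")
    t0 = record.timestamps[0]
    n_out = int(np.floor((record.timestamps[-1] - t0) * target_rate)) + 1
    grid = t0 + np.arange(n_out) / target_rate
    spline = CubicSpline(record.timestamps, record.conductance, bc_type="natural")
    return UniformSeries(values=spline(grid), rate=target_rate, start_time=float(t0))


def median_filter_1s(series: UniformSeries, window: int = MEDIAN_WINDOW) -> UniformSeries:
    """Centered running median; edge windows shrink to the available samples."""
    vals = (
        pd.Series(series.values)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return UniformSeries(values=vals, rate=series.rate, start_time=series.start_time)


def downsample_to_2hz(series: UniformSeries) -> UniformSeries:
    """Decimate a 4 Hz series by 2 (the median filter did the smoothing)."""
    if not np.isclose(series.rate, INTERMEDIATE_RATE):
        raise ValidationError(f"expected a {INTERMEDIATE_RATE:g} Hz series")
    return UniformSeries(values=series.values[::2], rate=series.rate / 2.0, start_time=series.start_time)


def _highpass_ba(rate: float) -> tuple[np.ndarray, np.ndarray]:
    return butter(2, HIGHPASS_CUTOFF, btype="highpass", fs=rate)


def highpass_001(series: UniformSeries) -> PreprocessedEDA:
    """Zero-phase 2nd-order Butterworth high-pass at 0.01 Hz."""
    b, a = _highpass_ba(series.rate)
    padlen = 3 * max(len(a), len(b))
    if len(series) <= padlen:
        raise ValidationError(f"series too short for high-pass filtering (need > {padlen} samples)")
    vals = filtfilt(b, a, series.values)
    return PreprocessedEDA(values=vals, rate=series.rate, start_time=series.start_time)


def highpass_001_causal(values: np.ndarray, rate: float, zi: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass causal high-pass, for streaming.  Returns (output, state).

    On the first call (``zi=None``) the filter state is initialized for a step
    input at the first sample value, which avoids a large start-up transient.
    """
    b, a = _highpass_ba(rate)
    if zi is None:
        zi = lfilter_zi(b, a) * (values[0] if len(values) else 0.0)
    out, zf = lfilter(b, a, values, zi=zi)
    return out, zf


def preprocess_eda(record: RawEDARecord) -> PreprocessedEDA:
    """Full batch chain: spline 4 Hz -> median 1 s -> 2 Hz -> high-pass 0.01 Hz."""
    if record.duration < 60.0:
        raise ValidationError("recording must span at least 60 s")
    s4 = resample_cubic_spline(record, INTERMEDIATE_RATE)
    s4 = median_filter_1s(s4)
    s2 = downsample_to_2hz(s4)
    return highpass_001(s2)
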