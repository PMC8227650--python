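"""Variable frequency complex demodulation (VFCDM).

A two-stage time-frequency decomposition of a real signal into narrow-band
components with time-varying center frequencies.  Stage one is ordinary
(fixed-frequency) complex demodulation: the signal is shifted by
``exp(-j 2 pi f0 t)`` at each band center ``f0`` and low-pass filtered,
yielding a complex envelope whose magnitude and angle give the band's
instantaneous amplitude and phase.  Stage two re-demodulates each band-limited
signal along its *estimated instantaneous-frequency track* (the band center
plus the scaled phase derivative), which sharpens amplitude and phase
estimates when the underlying oscillation drifts within the band.

For 2 Hz EDA the band centers run from 0.04 to 0.92 Hz in 0.08 Hz steps
(12 contiguous bands of +/-0.04 Hz half-width).  The sympathetic-dynamics
bands consumed by TVSymp are components 2 and 3 (centers 0.12 and 0.20 Hz,
covering roughly 0.08-0.24 Hz).  The first band retains the low-frequency /
DC-adjacent content; it is computed but never used by the indices.

Filter design.  The band-splitting low-pass is a 65-tap FIR whose frequency
response is a raised cosine (Hann shape in frequency): gain
``cos^2(pi f / (2 W))`` up to the zero at ``W`` = the band spacing, hence
-6 dB at half the spacing.  Shifted copies of this response at the 12 centers
sum to exactly one across the analysis range, so the stage-one filterbank is
a partition of unity and the component sum reconstructs the input.  The
filter is applied once as a centered convolution (linear phase, zero delay).
Stage two uses the same shape at twice the width: its only job is to reject
the double-frequency demodulation image, and a wider passband avoids
re-attenuating in-band content relative to the moving track.  A final
residual-correction pass routes the small stage-two reconstruction error back
through the stage-one filterbank so the decomposition stays near-lossless for
signals band-limited below the last band edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .records import UniformSeries, ValidationError, VFCDMDecomposition

F0_FIRST = 0.04  #: Hz, first band center
F_STEP = 0.08  #: Hz, band spacing = stage-one filter half-width
N_BANDS = 12  #: centers 0.04 .. 0.92 Hz
LPF_TAPS = 65  #: odd so the centered FIR is exactly zero-phase
EDGE_SECONDS = 10.0  #: filter warm-up span; component edges are transient

#: Amplitude floor (relative to the band maximum) below which the phase
#: derivative is considered undefined and the track falls back to f0.
_AMP_FLOOR = 1e-8


def band_centers(n_bands: int = N_BANDS) -> np.ndarray:
    return F0_FIRST + F_STEP * np.arange(n_bands)


def _raised_cosine_taps(rate: float, width: float, numtaps: int = LPF_TAPS) -> np.ndarray:
    """Linear-phase FIR with raised-cosine response: zero gain beyond ``width`` Hz.

    Gain is ``cos^2(pi f / (2 width))`` for ``|f| <= width`` (-6 dB at
    ``width/2``), the full-rolloff raised-cosine pulse; its ``1/t^3`` tail
    makes a 65-tap truncation essentially exact.
    """
    n = np.arange(numtaps) - (numtaps - 1) / 2
    x = (n / rate) * width  # t / T with T = 1/width
    den = 1.0 - (2.0 * x) ** 2
    safe = np.where(np.abs(den) < 1e-10, 1.0, den)
    h = np.where(
        np.abs(den) < 1e-10,
        np.pi / 4.0 * np.sinc(0.5),
        np.sinc(x) * np.cos(np.pi * x) / safe,
    )
    return h / h.sum()


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Centered FIR convolution with reflected ends (zero phase, no delay)."""
    half = (len(taps) - 1) // 2
    if len(x) <= half + 1:
        raise ValidationError("series shorter than the low-pass filter half-length")
    padded = np.concatenate([x[half:0:-1], x, x[-2 : -half - 2 : -1]])
    return np.convolve(padded, taps, mode="valid")


def _lowpass_complex(z: np.ndarray, taps: np.ndarray) -> np.ndarray:
    return _zero_phase_fir(z.real, taps) + 1j * _zero_phase_fir(z.imag, taps)


@dataclass(frozen=True)
class ComplexEnvelope:
    """Complex demodulate of one band: raw product ``z`` and low-passed ``zlp``.

    ``amplitude`` is ``2 |zlp|`` and ``phase`` is ``angle(zlp)``; together with
    the center frequency they express the band content as
    ``A(t) cos(2 pi f0 t + phi(t))``.
    """

    z: np.ndarray
    zlp: np.ndarray
    f0: float
    rate: float
    start_time: float = 0.0

    @property
    def amplitude(self) -> np.ndarray:
        return 2.0 * np.abs(self.zlp)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.zlp)

    def band_signal(self) -> np.ndarray:
        """Real band-limited signal ``A(t) cos(2 pi f0 t + phi(t))``."""
        t = np.arange(self.zlp.size) / self.rate
        return self.amplitude * np.cos(2.0 * np.pi * self.f0 * t + self.phase)


def fixed_demodulate(
    series: UniformSeries, f0: float, bandwidth: float = F_STEP, numtaps: int = LPF_TAPS
) -> ComplexEnvelope:
    """Stage-one complex demodulation at a fixed center frequency.

    Multiplies the signal by ``exp(-j 2 pi f0 t)`` and low-passes with the
    raised-cosine prototype of half-width ``bandwidth`` (-6 dB at
    ``bandwidth/2 < f0``), isolating content in ``f0 +/- bandwidth``.
    """
    if not 0 < f0 < series.rate / 2.0:
        raise ValidationError("f0 must lie strictly inside (0, Nyquist)")
    if bandwidth <= 0 or bandwidth > F_STEP + 1e-12:
        raise ValidationError("bandwidth must be in (0, band spacing]")
    t = np.arange(len(series)) / series.rate
    z = series.values * np.exp(-2j * np.pi * f0 * t)
    zlp = _lowpass_complex(z, _raised_cosine_taps(series.rate, bandwidth, numtaps))
    return ComplexEnvelope(z=z, zlp=zlp, f0=f0, rate=series.rate, start_time=series.start_time)


def instantaneous_frequency(envelope: ComplexEnvelope, smooth: bool = True) -> np.ndarray:
    """Frequency track ``f(t) = f0 + (1/2pi) dphi/dt`` of a demodulated band.

    The phase is unwrapped and differentiated with central differences.  Where
    the envelope amplitude is numerically zero the phase derivative is
    undefined and set to 0 (track falls back to the band center).  The track
    is optionally smoothed with the band-splitting low-pass and clipped to
    ``[0, Nyquist]``.
    """
    amp = np.abs(envelope.zlp)
    phase = np.unwrap(np.angle(envelope.zlp))
    dphi = np.gradient(phase) * envelope.rate  # rad/s
    floor = _AMP_FLOOR * max(float(amp.max()), 1e-300)
    dphi[amp <= floor] = 0.0
    if smooth:
        dphi = _zero_phase_fir(dphi, _raised_cosine_taps(envelope.rate, F_STEP))
    f = envelope.f0 + dphi / (2.0 * np.pi)
    return np.clip(f, 0.0, envelope.rate / 2.0)


def variable_demodulate(
    series: UniformSeries, freq_track: np.ndarray, bandwidth: float = F_STEP, numtaps: int = LPF_TAPS
) -> np.ndarray:
    """Stage-two demodulation along a time-varying frequency track.

    Demodulates with the cumulative phase ``Phi(t) = 2 pi int_0^t f(tau) dtau``
    (trapezoidal rule), low-passes at half-width ``bandwidth``, and
    reconstructs the real component
    ``A(t) cos(Phi(t) + phi(t)) = 2 Re[zlp(t) exp(j Phi(t))]``.

    With a constant track ``f(t) = f0`` this reduces exactly to the
    fixed-frequency demodulation (the trapezoidal integral of a constant is
    the exact linear phase).
    """
    freq_track = np.asarray(freq_track, dtype=float)
    if freq_track.shape != (len(series),):
        raise ValidationError("freq_track must have the same length as the series")
    t = np.arange(len(series)) / series.rate
    phi_int = 2.0 * np.pi * cumulative_trapezoid(freq_track, t, initial=0.0)
    z = series.values * np.exp(-1j * phi_int)
    zlp = _lowpass_complex(z, _raised_cosine_taps(series.rate, bandwidth, numtaps))
    return 2.0 * np.real(zlp * np.exp(1j * phi_int))


def analytic_component(series: UniformSeries, band: int, numtaps: int = LPF_TAPS) -> np.ndarray:
    """Complex analytic form of one refined VFCDM component.

    Returns ``2 zlp(t) exp(j Phi(t))`` whose real part is the band component
    and whose magnitude is the band's instantaneous amplitude.  Because the
    quadrature comes from the demodulation itself (a local FIR operation),
    this avoids the circular-FFT wraparound of a discrete Hilbert transform —
    which matters on the short windows used in streaming.
    """
    f0 = band_centers()[band]
    env = fixed_demodulate(series, f0, F_STEP, numtaps)
    track = np.clip(instantaneous_frequency(env), f0 - F_STEP / 2.0, f0 + F_STEP / 2.0)
    t = np.arange(len(series)) / series.rate
    phi_int = 2.0 * np.pi * cumulative_trapezoid(track, t, initial=0.0)
    z = env.band_signal() * np.exp(-1j * phi_int)
    zlp = _lowpass_complex(z, _raised_cosine_taps(series.rate, 2.0 * F_STEP, numtaps))
    return 2.0 * zlp * np.exp(1j * phi_int)


def vfcdm_decompose(
    series: UniformSeries,
    n_bands: int = N_BANDS,
    numtaps: int = LPF_TAPS,
    residual_correction: bool = True,
) -> VFCDMDecomposition:
    """Full two-stage VFCDM decomposition into ``n_bands`` components.

    Per band: stage-one demodulation at the fixed center, instantaneous-
    frequency estimation (clipped to the band's own span so components stay
    inside their bands), then stage-two re-demodulation of the *stage-one
    band signal* along the track with a double-width low-pass.  A final
    residual pass feeds ``input - sum(components)`` back through the
    stage-one filterbank and adds each band's share to its component, keeping
    the decomposition near-lossless.
    """
    if len(series) < 50:
        raise ValidationError("need at least 50 samples (25 s at 2 Hz) for VFCDM")
    centers = band_centers(n_bands)
    components = np.empty((n_bands, len(series)))
    for k, f0 in enumerate(centers):
        env = fixed_demodulate(series, f0, F_STEP, numtaps)
        track = instantaneous_frequency(env)
        track = np.clip(track, f0 - F_STEP / 2.0, f0 + F_STEP / 2.0)
        band_series = UniformSeries(values=env.band_signal(), rate=series.rate, start_time=series.start_time)
        components[k] = variable_demodulate(band_series, track, 2.0 * F_STEP, numtaps)
    if residual_correction:
        residual = series.values - components.sum(axis=0)
        res_series = UniformSeries(values=residual, rate=series.rate, start_time=series.start_time)
        for k, f0 in enumerate(centers):
            components[k] += fixed_demodulate(res_series, f0, F_STEP, numtaps).band_signal()
    return VFCDMDecomposition(
        components=components,
        center_frequencies=centers,
        rate=series.rate,
        start_time=series.start_time,
    )
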