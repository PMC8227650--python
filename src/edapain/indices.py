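"""The three real-time EDA pain indices: TVSymp, MTVSymp and dPhEDA.

* **TVSymp** (time-varying index of sympathetic activity): the VFCDM
  components 2 and 3 (~0.08-0.24 Hz, the sympathetic-dynamics band) are
  summed, normalized to unit variance, and the instantaneous amplitude of the
  resulting narrow-band signal is taken via the Hilbert transform.
* **MTVSymp** (modified TVSymp): TVSymp minus its trailing ``k``-second mean,
  floored at zero — an edge detector for abrupt sympathetic surges, which is
  what a short pain stimulus produces.
* **dPhEDA**: the five-point-stencil time derivative of the cvxEDA phasic
  component (microsiemens per second).

All three run at 2 Hz, the rate of the preprocessed EDA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .records import UniformSeries, ValidationError, VFCDMDecomposition

MTVSYMP_WINDOW_S = 5.0  #: trailing-mean window, seconds
TVSYMP_BANDS = (1, 2)  #: 0-based indices of VFCDM components 2 and 3


def hilbert_amplitude(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous amplitude and phase of a real series via the analytic signal.

    The analytic signal ``Z = x + i*H[x]`` (discrete Hilbert transform
    approximating the Cauchy principal-value integral) gives amplitude
    ``|Z| = sqrt(x^2 + H[x]^2)`` and phase ``arg Z``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValidationError("need at least 16 samples for the analytic signal")
    z = hilbert(x)
    return np.abs(z), np.angle(z)


@dataclass(frozen=True)
class TVSympSeries:
    """TVSymp with its intermediate quantities.

    ``x_prime`` is the unit-variance sum of the sympathetic-band components,
    ``amplitude`` (= TVSymp) and ``phase`` come from its analytic signal.
    """

    x_prime: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    rate: float
    start_time: float = 0.0

    @property
    def values(self) -> np.ndarray:
        return self.amplitude

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.amplitude.size) / self.rate


def tvsymp(decomp: VFCDMDecomposition, bands: tuple[int, ...] = TVSYMP_BANDS) -> TVSympSeries:
    """TVSymp from a VFCDM decomposition.

    Sums the selected components (defaults: components 2 and 3, the
    ~0.08-0.24 Hz sympathetic dynamics), scales the sum to unit sample
    variance (the components are zero-mean band-pass signals, so the mean is
    not subtracted), and takes the Hilbert instantaneous amplitude.
    """
    if decomp.n_bands < max(bands) + 1:
        raise ValidationError("decomposition does not contain the sympathetic bands")
    summed = decomp.components[list(bands)].sum(axis=0)
    sd = summed.std(ddof=1)
    if sd == 0:
        raise ValidationError("degenerate input: sympathetic-band sum has zero variance")
    x_prime = summed / sd
    amp, phase = hilbert_amplitude(x_prime)
    return TVSympSeries(
        x_prime=x_prime, amplitude=amp, phase=phase, rate=decomp.rate, start_time=decomp.start_time
    )


def mtvsymp_values(a: np.ndarray, rate: float, k: float = MTVSYMP_WINDOW_S) -> np.ndarray:
    """MTVSymp from a TVSymp amplitude array.

    For each sample ``t`` the trailing mean ``mu_t`` of the previous
    ``k * rate`` samples (indices ``t - k*rate .. t - 1``) is subtracted and
    the result floored at zero.  During warm-up (``t < k*rate``) the mean of
    all available previous samples is used; the first output is 0 by
    convention (no history exists).
    """
    win = int(round(k * rate))
    if win < 1:
        raise ValidationError("k * rate must be at least 1 sample")
    a = np.asarray(a, dtype=float)
    if a.size <= win:
        raise ValidationError("series must be longer than the trailing window")
    csum = np.concatenate([[0.0], np.cumsum(a)])
    idx = np.arange(a.size)
    lo = np.maximum(idx - win, 0)
    counts = idx - lo
    mu = np.zeros(a.size)
    nz = counts > 0
    mu[nz] = (csum[idx[nz]] - csum[lo[nz]]) / counts[nz]
    out = np.where(mu <= a, a - mu, 0.0)
    out[0] = 0.0
    return out


def mtvsymp(tv: TVSympSeries, k: float = MTVSYMP_WINDOW_S) -> UniformSeries:
    """MTVSymp series from a TVSymp series (trailing window ``k`` seconds)."""
    vals = mtvsymp_values(tv.amplitude, tv.rate, k)
    return UniformSeries(values=vals, rate=tv.rate, start_time=tv.start_time)


def dpheda(phasic: np.ndarray, rate: float = 2.0) -> np.ndarray:
    """Five-point-stencil time derivative of the phasic component.

    Interior samples use
    ``(x[n-2] - 8 x[n-1] + 8 x[n+1] - x[n+2]) / (12 / Fs)`` — exact for
    polynomials through degree 4; the two samples at each end are handled by
    replicate-padding the series, which keeps the output aligned with the
    input for segment extraction.
    """
    x = np.asarray(phasic, dtype=float)
    if x.size < 5:
        raise ValidationError("need at least 5 samples for the five-point stencil")
    xp = np.concatenate([x[:1], x[:1], x, x[-1:], x[-1:]])
    return (xp[:-4] - 8.0 * xp[1:-3] + 8.0 * xp[3:-1] - xp[4:]) / (12.0 / rate)


def dpheda_series(decomp_phasic: np.ndarray, rate: float = 2.0, start_time: float = 0.0) -> UniformSeries:
    """dPhEDA as a :class:`UniformSeries` (microsiemens per second)."""
    return UniformSeries(values=dpheda(decomp_phasic, rate), rate=rate, start_time=start_time)
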