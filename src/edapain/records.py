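"""Core data containers shared by every pipeline stage.

Electrodermal activity (EDA, skin conductance in microsiemens) arrives from a
wearable as an irregularly timestamped stream; all analysis downstream of
preprocessing runs on uniformly sampled series at 2 Hz.  The containers here
are deliberately thin: a validated ``numpy`` array plus the minimal metadata
(subject id, rate, start time) each stage needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when a record or series violates its structural invariants."""


@dataclass(frozen=True)
class RawEDARecord:
    """One subject's raw skin-conductance trace with its timestamps.

    Parameters
    ----------
    subject_id : str
        Identifier of the recorded subject.
    timestamps : ndarray of float
        Sample times in seconds, strictly increasing, possibly irregular.
    conductance : ndarray of float
        Skin conductance in microsiemens, finite and nonnegative.
    """

    subject_id: str
    timestamps: np.ndarray
    conductance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        c = np.asarray(self.conductance, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.shape != c.shape:
            raise ValidationError("timestamps and conductance must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValidationError("a recording needs at least 2 samples")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
            raise ValidationError("timestamps and conductance must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if np.any(c < 0):
            raise ValidationError("conductance must be nonnegative")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "conductance", c)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class StimulusEventList:
    """Stimulus onset times (seconds) for one subject, sorted ascending."""

    subject_id: str
    event_times: np.ndarray

    def __post_init__(self) -> None:
        e = np.sort(np.asarray(self.event_times, dtype=float).ravel())
        if e.size and (not np.all(np.isfinite(e)) or np.any(e < 0)):
            raise ValidationError("event times must be finite and nonnegative")
        object.__setattr__(self, "event_times", e)

    def __len__(self) -> int:
        return self.event_times.size


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled series: values, rate (Hz) and absolute start time."""

    values: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValidationError("values must be a 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValidationError("values must be finite")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        object.__setattr__(self, "values", v)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate

    def __len__(self) -> int:
        return self.values.size


#: Alias used for the output of the full preprocessing chain (2 Hz, highpassed).
PreprocessedEDA = UniformSeries


@dataclass(frozen=True)
class VFCDMDecomposition:
    """Narrow-band components from variable frequency complex demodulation.

    ``components`` is an ``(n_bands, n_samples)`` matrix of real band signals;
    ``center_frequencies`` holds the nominal band centers in Hz.  The sum of
    the rows approximately reconstructs the analyzed signal.
    """

    components: np.ndarray
    center_frequencies: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        comp = np.atleast_2d(np.asarray(self.components, dtype=float))
        freqs = np.asarray(self.center_frequencies, dtype=float)
        if comp.shape[0] != freqs.size:
            raise ValidationError("one center frequency per component required")
        object.__setattr__(self, "components", comp)
        object.__setattr__(self, "center_frequencies", freqs)

    @property
    def n_bands(self) -> int:
        return self.components.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Sum of all band components."""
        return self.components.sum(axis=0)


@dataclass(frozen=True)
class EDADecomposition:
    """Tonic/phasic split of a conductance series (cvxEDA model).

    Invariant: ``phasic + tonic + residual`` equals the input exactly, and the
    sudomotor ``driver`` is nonnegative up to solver tolerance.
    """

    phasic: np.ndarray
    tonic: np.ndarray
    driver: np.ndarray
    residual: np.ndarray
    rate: float
    start_time: float = 0.0


@dataclass(frozen=True)
class IndexSeries(UniformSeries):
    """A TVSymp, MTVSymp, or dPhEDA time series at 2 Hz."""

    name: str = ""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic EDA generator.

    The generator emulates a pain-stimulation session: a slowly drifting tonic
    level, one evoked skin-conductance response (SCR) per stimulus, spontaneous
    SCRs, measurement noise, and irregular raw sampling timestamps.

    Attributes
    ----------
    n_subjects : int
        Number of independent subjects to simulate.
    n_stimuli_per_subject : int
        Pain stimuli per subject (default 10, matching a repeated-stimulus
        session).
    isi_range : (float, float)
        Uniform range of inter-stimulus intervals, seconds.
    raw_rate : float
        Nominal raw sampling rate in Hz (default 120, wearable stream rate).
    jitter_frac : float
        Timestamp jitter as a fraction of the nominal sampling interval.
    tonic_level : float
        Baseline conductance, microsiemens.
    tonic_drift_sd : float
        Standard deviation of the tonic Gaussian random walk per sqrt-second.
    scr_amplitude_pain : float
        Mean evoked SCR amplitude (microsiemens); the pain effect size.
    scr_amplitude_sd : float
        Between-response SD of evoked amplitudes.
    scr_latency : float
        Seconds from stimulus onset to SCR onset.
    tau0, tau1 : float
        Bateman kernel time constants, seconds (slow decay, fast rise);
        requires ``tau0 > tau1 > 0``.
    spontaneous_scr_rate : float
        Poisson rate of non-stimulus SCRs, events per minute.
    spontaneous_amp_range : (float, float)
        Uniform amplitude range of spontaneous SCRs, microsiemens.
    noise_sd : float
        White measurement-noise SD, microsiemens.
    lead_in, lead_out : float
        Quiet seconds before the first and after the last stimulus.
    seed : int
        Master seed; per-subject streams are derived deterministically.
    """

    n_subjects: int = 10
    n_stimuli_per_subject: int = 10
    isi_range: tuple[float, float] = (30.0, 60.0)
    raw_rate: float = 120.0
    jitter_frac: float = 0.2
    tonic_level: float = 2.0
    tonic_drift_sd: float = 0.01
    scr_amplitude_pain: float = 0.5
    scr_amplitude_sd: float = 0.1
    scr_latency: float = 1.5
    tau0: float = 2.0
    tau1: float = 0.7
    spontaneous_scr_rate: float = 2.0
    spontaneous_amp_range: tuple[float, float] = (0.05, 0.3)
    noise_sd: float = 0.02
    lead_in: float = 60.0
    lead_out: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.tau0 <= self.tau1 or self.tau1 <= 0:
            raise ValidationError("require tau0 > tau1 > 0")
        if self.n_subjects < 0 or self.n_stimuli_per_subject < 0:
            raise ValidationError("counts must be nonnegative")
        for name in ("raw_rate",):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("tonic_drift_sd", "scr_amplitude_sd", "spontaneous_scr_rate", "noise_sd", "jitter_frac"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.isi_range[0] > self.isi_range[1] or self.isi_range[0] <= 0:
            raise ValidationError("isi_range must be a positive (low, high) pair")


@dataclass(frozen=True)
class SubjectGroundTruth:
    """Noise-free tonic and phasic traces on the raw timestamp grid."""

    tonic: np.ndarray
    phasic: np.ndarray
    noise: np.ndarray


@dataclass
class SyntheticDataset:
    """Per-subject records, stimulus events and generative ground truth."""

    config: SimulationConfig
    records: list[RawEDARecord] = field(default_factory=list)
    events: list[StimulusEventList] = field(default_factory=list)
    truths: list[SubjectGroundTruth] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)
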