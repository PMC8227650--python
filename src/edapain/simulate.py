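"""Synthetic EDA generator with known tonic/phasic ground truth.

Real skin-conductance recordings from pain-stimulation sessions are hard to
share; this module produces surrogate sessions whose generative components are
known exactly, so every downstream stage (preprocessing, decomposition,
indices, segmentation, statistics, classification) can be validated against
ground truth.

A simulated subject is the sum of four processes on an irregular timestamp
grid:

* a tonic baseline following a Gaussian random walk (clipped below at
  0.05 uS so conductance stays physiological),
* one evoked skin-conductance response (SCR) per pain stimulus — a Bateman
  bi-exponential kernel starting ``scr_latency`` seconds after the stimulus,
  with amplitude drawn from a truncated normal,
* spontaneous (non-specific) SCRs arriving as a Poisson process,
* white measurement noise.

Conductance is clipped at zero after summation; the clipping correction is
folded into the stored noise trace so the identity
``tonic + phasic + noise == conductance`` holds exactly.
"""

from __future__ import annotations

import numpy as np

from .records import (
    RawEDARecord,
    SimulationConfig,
    StimulusEventList,
    SubjectGroundTruth,
    SyntheticDataset,
    ValidationError,
)

_TONIC_FLOOR = 0.05  # uS; lowest plausible tonic level


def scr_kernel(t: np.ndarray | float, tau0: float = 2.0, tau1: float = 0.7) -> np.ndarray:
    """Bateman skin-conductance-response kernel.

    ``exp(-t/tau0) - exp(-t/tau1)`` for ``t >= 0`` and zero before onset:
    a fast rise governed by ``tau1`` and a slow decay governed by ``tau0``.

    Parameters
    ----------
    t : array-like
        Time since response onset, seconds.
    tau0, tau1 : float
        Decay and rise time constants, seconds; requires ``tau0 > tau1 > 0``.
    """
    if tau0 <= tau1 or tau1 <= 0:
        raise ValidationError("require tau0 > tau1 > 0")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = np.exp(-tp / tau0) - np.exp(-tp / tau1)
    return out


def _kernel_peak(tau0: float, tau1: float) -> float:
    """Maximum of the unnormalized Bateman kernel (used to scale amplitudes)."""
    tpk = (np.log(tau0) - np.log(tau1)) / (1.0 / tau1 - 1.0 / tau0)
    return float(np.exp(-tpk / tau0) - np.exp(-tpk / tau1))


def _subject_rng(config: SimulationConfig, subject_index: int) -> np.random.Generator:
    # Derive an independent, reproducible stream per subject from the master seed.
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(subject_index)]))


def generate_subject(
    config: SimulationConfig, subject_index: int
) -> tuple[RawEDARecord, StimulusEventList, SubjectGroundTruth]:
    """Simulate one subject's recording, stimulus times and ground truth."""
    config.validate()
    rng = _subject_rng(config, subject_index)

    # Stimulus schedule: lead-in, then n stimuli at random intervals.
    n_stim = config.n_stimuli_per_subject
    isis = rng.uniform(*config.isi_range, size=max(n_stim - 1, 0)) if n_stim else np.empty(0)
    event_times = config.lead_in + np.concatenate([[0.0], np.cumsum(isis)]) if n_stim else np.empty(0)
    duration = (event_times[-1] if n_stim else config.lead_in) + config.lead_out

    # Irregular timestamps: nominal grid plus uniform jitter, kept monotone.
    dt = 1.0 / config.raw_rate
    n = int(np.floor(duration * config.raw_rate)) + 1
    t = np.arange(n) * dt
    if config.jitter_frac > 0 and n > 2:
        jitter = rng.uniform(-config.jitter_frac * dt, config.jitter_frac * dt, size=n - 2)
        t[1:-1] += jitter  # endpoints fixed so the span is exact
    t = np.maximum.accumulate(t)
    t += np.arange(n) * 1e-12  # break exact ties from accumulate

    # Tonic: Gaussian random walk with per-step variance dt * sd^2.
    if config.tonic_drift_sd > 0:
        steps = rng.normal(0.0, config.tonic_drift_sd, size=n) * np.sqrt(np.maximum(np.diff(t, prepend=t[0]), 0.0))
        steps[0] = 0.0
        tonic = config.tonic_level + np.cumsum(steps)
    else:
        tonic = np.full(n, config.tonic_level)
    tonic = np.clip(tonic, _TONIC_FLOOR, None)

    peak = _kernel_peak(config.tau0, config.tau1)
    phasic = np.zeros(n)

    # Evoked SCRs: one per stimulus, amplitude ~ N(mu, sd) floored at 0,
    # scaled so `amplitude` is the peak height in uS.
    for ev in event_times:
        amp = max(rng.normal(config.scr_amplitude_pain, config.scr_amplitude_sd), 0.0)
        if amp > 0:
            phasic += (amp / peak) * scr_kernel(t - ev - config.scr_latency, config.tau0, config.tau1)

    # Spontaneous SCRs: Poisson arrivals over the whole recording.
    if config.spontaneous_scr_rate > 0:
        n_spont = rng.poisson(config.spontaneous_scr_rate * duration / 60.0)
        onsets = np.sort(rng.uniform(0.0, duration, size=n_spont))
        amps = rng.uniform(*config.spontaneous_amp_range, size=n_spont)
        for onset, amp in zip(onsets, amps):
            phasic += (amp / peak) * scr_kernel(t - onset, config.tau0, config.tau1)

    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    conductance = tonic + phasic + noise
    # Clip at zero; attribute the (rare) correction to the noise trace so the
    # additive ground-truth identity stays exact.
    clipped = np.clip(conductance, 0.0, None)
    noise = noise + (clipped - conductance)
    conductance = clipped

    record = RawEDARecord(subject_id=f"sim{subject_index:03d}", timestamps=t, conductance=conductance)
    events = StimulusEventList(subject_id=record.subject_id, event_times=event_times)
    truth = SubjectGroundTruth(tonic=tonic, phasic=phasic, noise=noise)
    return record, events, truth


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate ``config.n_subjects`` independent subjects."""
    config.validate()
    ds = SyntheticDataset(config=config)
    for i in range(config.n_subjects):
        record, events, truth = generate_subject(config, i)
        ds.records.append(record)
        ds.events.append(events)
        ds.truths.append(truth)
    return ds
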