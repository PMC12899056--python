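"""Synthetic multi-subject EEG cohorts with controlled domain shift.

Each subject gets 1/f^beta background noise with a subject-specific
amplitude gain and spectral profile. Seizure-group subjects additionally
carry rhythmic sinusoid-plus-harmonic bursts confined to focal channels,
and three simulated annotators produce per-second labels whose
disagreement is localized at burst boundaries.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawn keys, so any subject or stream can be
re-derived independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ELECTRODES, EEGRecording
from .preprocess import BIPOLAR_PAIRS

__all__ = [
    "SubjectProfile",
    "CohortConfig",
    "BurstEvent",
    "sample_burst_events",
    "generate_subject_recording",
    "simulate_annotators",
    "generate_cohort",
    "focal_bipolar_footprint",
]

#: reference background RMS in microvolts at amplitude_gain = 1
BASE_RMS_UV = 20.0
#: burst amplitude as a multiple of the subject's background RMS; bursts are
#: deliberately conspicuous so scaled-down training runs can learn them
BURST_SNR = 8.0


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    amplitude_gain: float
    spectral_tilt: float
    baseline_shift_hz: float
    focal_channels: frozenset[int]
    group: str  # "seizure" | "non_seizure"

    def __post_init__(self):
        if self.group not in ("seizure", "non_seizure"):
            raise InvalidConfigError(f"unknown group {self.group!r}")
        if self.amplitude_gain <= 0:
            raise InvalidConfigError("amplitude_gain must be positive")
        if any(c < 0 or c > 17 for c in self.focal_channels):
            raise InvalidConfigError("focal channel indices must lie in [0, 17]")
        if (self.group == "seizure") != bool(self.focal_channels):
            raise InvalidConfigError("focal_channels must be non-empty iff group is seizure")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects_per_group: int = 15
    duration_s: float = 300.0
    fs: float = 256.0
    burst_rate: float = 2.0  # expected bursts per minute
    burst_dur_range_s: tuple[float, float] = (3.0, 10.0)
    burst_freq_range_hz: tuple[float, float] = (2.0, 13.0)
    annotator_flip_prob: float = 0.2
    amplitude_gain_range: tuple[float, float] = (1.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        if self.duration_s < 2.0:
            raise InvalidConfigError("duration_s must be at least 2 s (one window)")
        lo, hi = self.burst_freq_range_hz
        if not (0.5 <= lo <= hi <= 30.0):
            raise InvalidConfigError("burst_freq_range_hz must lie within [0.5, 30] Hz")
        if not 0.0 <= self.annotator_flip_prob <= 1.0:
            raise InvalidConfigError("annotator_flip_prob must be a probability")
        if self.n_subjects_per_group < 1:
            raise InvalidConfigError("n_subjects_per_group must be >= 1")
        if self.burst_rate < 0:
            raise InvalidConfigError("burst_rate must be non-negative")


@dataclass(frozen=True)
class BurstEvent:
    t_start_s: float
    duration_s: float
    freq_hz: float


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def sample_burst_events(config: CohortConfig, rng: np.random.Generator) -> list[BurstEvent]:
    """Draw a Poisson number of bursts with uniform times, durations, frequencies.

    Exposed so tests can replay the event stream independently.
    """
    expected = config.burst_rate * config.duration_s / 60.0
    count = int(rng.poisson(expected))
    events = []
    for _ in range(count):
        dur = float(rng.uniform(*config.burst_dur_range_s))
        dur = min(dur, config.duration_s)
        t0 = float(rng.uniform(0.0, config.duration_s - dur))
        freq = float(rng.uniform(*config.burst_freq_range_hz))
        events.append(BurstEvent(t0, dur, freq))
    return events


def _colored_background(profile: SubjectProfile, n_samples: int, fs: float,
                        rng: np.random.Generator) -> np.ndarray:
    """19-channel 1/f^beta noise with a resonance bump, unit-RMS then gain-scaled."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = (freqs + 1.0) ** (-profile.spectral_tilt / 2.0)
    bump = 1.0 + 2.0 * np.exp(-0.5 * ((freqs - profile.baseline_shift_hz) / 1.5) ** 2)
    shape = shape * bump
    shape[0] = 0.0  # zero-mean signal
    white = rng.standard_normal((len(ELECTRODES), n_samples))
    spec = np.fft.rfft(white, axis=1) * shape
    sig = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt((sig ** 2).mean(axis=1, keepdims=True))
    sig /= np.maximum(rms, 1e-30)
    return sig * BASE_RMS_UV * profile.amplitude_gain


def _truth_from_events(events: list[BurstEvent], t_seconds: int) -> np.ndarray:
    truth = np.zeros(t_seconds, dtype=np.int8)
    for ev in events:
        first = int(np.floor(ev.t_start_s))
        last = int(np.ceil(ev.t_start_s + ev.duration_s))
        truth[max(first, 0):min(last, t_seconds)] = 1
    return truth


def focal_bipolar_footprint(focal_channels: frozenset[int] | set[int]) -> set[int]:
    """Bipolar channels that see energy planted for the given focal channels.

    Bursts are planted differentially on the electrode pair of each focal
    bipolar channel, so every bipolar channel sharing one of those
    electrodes also picks up half-amplitude leakage.
    """
    electrodes: set[str] = set()
    for c in focal_channels:
        a, b = BIPOLAR_PAIRS[c]
        electrodes.update((a, b))
    return {i for i, (a, b) in enumerate(BIPOLAR_PAIRS)
            if a in electrodes or b in electrodes}


def generate_subject_recording(profile: SubjectProfile, config: CohortConfig,
                               seed: int) -> EEGRecording:
    """Synthesize one subject: background + (optionally) planted bursts + annotators."""
    if config.duration_s < 2.0:
        raise InvalidConfigError("duration_s must be at least 2 s")
    n_samples = int(round(config.duration_s * config.fs))
    t_seconds = int(n_samples // config.fs)
    electrode_index = {name: i for i, name in enumerate(ELECTRODES)}

    signal = _colored_background(profile, n_samples, config.fs, _rng(seed, 0))

    events: list[BurstEvent] = []
    if profile.group == "seizure" and config.burst_rate > 0:
        events = sample_burst_events(config, _rng(seed, 1))
        for ev in events:
            i0 = int(round(ev.t_start_s * config.fs))
            n = int(round(ev.duration_s * config.fs))
            n = min(n, n_samples - i0)
            t = np.arange(n) / config.fs
            env = np.hanning(n)
            amp = BURST_SNR * BASE_RMS_UV * profile.amplitude_gain
            wave = amp * env * (np.sin(2 * np.pi * ev.freq_hz * t)
                                + 0.5 * np.sin(4 * np.pi * ev.freq_hz * t))
            for c in sorted(profile.focal_channels):
                a, b = BIPOLAR_PAIRS[c]
                signal[electrode_index[a], i0:i0 + n] += wave / 2.0
                signal[electrode_index[b], i0:i0 + n] -= wave / 2.0

    truth = _truth_from_events(events, t_seconds)
    annotations = simulate_annotators(truth, config.annotator_flip_prob, _rng(seed, 2))
    return EEGRecording(subject_id=profile.subject_id, signal=signal, fs=config.fs,
                        annotations=annotations, truth_mask=truth)


def simulate_annotators(truth_mask: np.ndarray, flip_prob: float,
                        rng_or_seed: np.random.Generator | int) -> np.ndarray:
    """Three noisy annotators: independent flips only at boundary-adjacent seconds."""
    if not 0.0 <= flip_prob <= 1.0:
        raise InvalidConfigError("flip_prob must lie in [0, 1]")
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    truth = np.asarray(truth_mask, dtype=np.int8)
    t = truth.shape[0]
    if t == 0:
        return np.zeros((3, 0), dtype=np.int8)
    boundary = np.zeros(t, dtype=bool)
    diff = truth[1:] != truth[:-1]
    boundary[1:] |= diff
    boundary[:-1] |= diff
    annotations = np.tile(truth, (3, 1))
    if flip_prob > 0 and boundary.any():
        idx = np.flatnonzero(boundary)
        flips = rng.random((3, idx.size)) < flip_prob
        for e in range(3):
            sel = idx[flips[e]]
            annotations[e, sel] = 1 - annotations[e, sel]
    return annotations


def _draw_profile(i: int, group: str, config: CohortConfig) -> SubjectProfile:
    rng = _rng(config.seed, i, 0)
    gain = float(rng.uniform(*config.amplitude_gain_range))
    tilt = float(rng.uniform(0.5, 1.5))
    baseline = float(rng.uniform(2.0, 8.0))
    if group == "seizure":
        n_focal = int(rng.integers(2, 5))
        focal = frozenset(int(c) for c in rng.choice(18, size=n_focal, replace=False))
        sid = f"sz{i + 1:02d}"
    else:
        focal = frozenset()
        sid = f"ns{i + 1 - config.n_subjects_per_group:02d}"
    return SubjectProfile(subject_id=sid, amplitude_gain=gain, spectral_tilt=tilt,
                          baseline_shift_hz=baseline, focal_channels=focal, group=group)


def cohort_profiles(config: CohortConfig) -> list[SubjectProfile]:
    n = config.n_subjects_per_group
    return [_draw_profile(i, "seizure" if i < n else "non_seizure", config)
            for i in range(2 * n)]


def generate_cohort(config: CohortConfig) -> list[EEGRecording]:
    """2 x n_subjects_per_group recordings, reproducible from config.seed alone."""
    recordings = []
    for i, profile in enumerate(cohort_profiles(config)):
        subject_seed = int(np.random.SeedSequence(config.seed, spawn_key=(i,)).generate_state(1)[0])
        recordings.append(generate_subject_recording(profile, config, subject_seed))
    return recordings
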