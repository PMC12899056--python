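"""Raw 19-electrode recordings -> normalized 18 x 33 x 17 log-STFT window tensors.

Pipeline: bipolar montage derivation, 256 -> 128 Hz downsampling, 2-s window
segmentation with centre-second consensus labels, Hann/64-point/hop-16 STFT
log-magnitude, and train-set global z-score normalization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data import EEGRecording

__all__ = [
    "BIPOLAR_PAIRS",
    "BIPOLAR_NAMES",
    "BipolarRecording",
    "WindowSet",
    "SpectrogramBatch",
    "NormStats",
    "MontageError",
    "derive_bipolar_montage",
    "downsample_signal",
    "segment_windows",
    "stft_logmag",
    "fit_zscore",
    "apply_zscore",
    "WINDOW_SECONDS",
    "TARGET_FS",
    "N_FFT",
    "HOP",
    "N_FREQ_BINS",
    "N_TIME_FRAMES",
    "LOG_FLOOR",
]

#: fixed bipolar channel order (longitudinal "double banana" plus midline)
BIPOLAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fz", "Cz"), ("Cz", "Pz"),
)
BIPOLAR_NAMES: tuple[str, ...] = tuple(f"{a}-{b}" for a, b in BIPOLAR_PAIRS)

WINDOW_SECONDS = 2.0
SOURCE_FS = 256.0
TARGET_FS = 128.0
N_FFT = 64
HOP = 16
N_FREQ_BINS = N_FFT // 2 + 1   # 33
N_TIME_FRAMES = int(WINDOW_SECONDS * TARGET_FS) // HOP + 1  # 17
LOG_FLOOR = 1e-8


class MontageError(ValueError):
    pass


class UnsupportedRateError(ValueError):
    pass


class LeakageError(RuntimeError):
    pass


@dataclass
class BipolarRecording:
    subject_id: str
    signal: np.ndarray  # 18 x T_samples, microvolts
    fs: float
    channel_names: tuple[str, ...] = field(default=BIPOLAR_NAMES)

    def __post_init__(self):
        if self.signal.shape[0] != len(BIPOLAR_NAMES):
            raise MontageError(f"expected {len(BIPOLAR_NAMES)} bipolar channels, "
                               f"got {self.signal.shape[0]}")


@dataclass
class WindowSet:
    """Segmented 2-s windows with per-window consensus labels."""

    windows: np.ndarray          # N x 18 x 256
    labels: np.ndarray           # N, binary
    subject_ids: np.ndarray      # N, str
    start_times_s: np.ndarray    # N
    split_role: str              # "train" | "eval"

    def __post_init__(self):
        if self.split_role not in ("train", "eval"):
            raise ValueError("split_role must be 'train' or 'eval'")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        roles = {s.split_role for s in sets}
        if len(roles) != 1:
            raise ValueError("cannot concatenate window sets with mixed roles")
        return WindowSet(
            windows=np.concatenate([s.windows for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
            start_times_s=np.concatenate([s.start_times_s for s in sets]),
            split_role=roles.pop(),
        )

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(self.windows[idx], self.labels[idx], self.subject_ids[idx],
                         self.start_times_s[idx], self.split_role)


@dataclass
class SpectrogramBatch:
    tensor: np.ndarray  # N x 18 x 33 x 17
    normalized: bool = False

    def __post_init__(self):
        if self.tensor.ndim != 4 or self.tensor.shape[2] != N_FREQ_BINS \
                or self.tensor.shape[3] != N_TIME_FRAMES:
            raise ValueError(f"expected N x C x {N_FREQ_BINS} x {N_TIME_FRAMES} tensor, "
                             f"got {self.tensor.shape}")


@dataclass
class NormStats:
    """Global z-score statistics, fitted on training-role data only."""

    mean: float
    std: float
    fitted_subject_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"mean": self.mean, "std": self.std,
                "fitted_subject_ids": list(self.fitted_subject_ids)}

    @staticmethod
    def from_dict(d: dict) -> "NormStats":
        return NormStats(float(d["mean"]), float(d["std"]),
                         tuple(d["fitted_subject_ids"]))


def derive_bipolar_montage(rec: EEGRecording) -> BipolarRecording:
    """Channel c = potential(first electrode) - potential(second electrode)."""
    lookup = {name.lower(): i for i, name in enumerate(rec.electrode_names)}
    rows = []
    for a, b in BIPOLAR_PAIRS:
        for name in (a, b):
            if name.lower() not in lookup:
                raise MontageError(f"electrode {name!r} missing from recording "
                                   f"{rec.subject_id!r}")
        rows.append(rec.signal[lookup[a.lower()]] - rec.signal[lookup[b.lower()]])
    return BipolarRecording(subject_id=rec.subject_id, signal=np.stack(rows), fs=rec.fs)


def downsample_signal(x: BipolarRecording) -> BipolarRecording:
    """256 -> 128 Hz: zero-phase anti-alias low-pass, then decimation by 2."""
    if x.fs != SOURCE_FS:
        raise UnsupportedRateError(f"downsampling expects {SOURCE_FS:g} Hz input, "
                                   f"got {x.fs:g} Hz")
    down = sps.decimate(x.signal, 2, axis=1, ftype="fir", zero_phase=True)
    return BipolarRecording(subject_id=x.subject_id, signal=down, fs=TARGET_FS)


def segment_windows(x: BipolarRecording, consensus: np.ndarray, role: str) -> WindowSet:
    """Slice 2-s windows; train role strides 1 s (50% overlap), eval strides 2 s.

    The label of window [t0, t0+2) is the consensus at its central second,
    fixed as second index t0+1. Windows running past the signal or past the
    consensus track are dropped.
    """
    if role not in ("train", "eval"):
        raise ValueError("role must be 'train' or 'eval'")
    if x.fs != TARGET_FS:
        raise UnsupportedRateError(f"segmentation expects {TARGET_FS:g} Hz input")
    consensus = np.asarray(consensus)
    win_len = int(WINDOW_SECONDS * x.fs)
    total_s = int(x.signal.shape[1] // x.fs)
    if total_s < WINDOW_SECONDS:
        warnings.warn(f"recording {x.subject_id!r} shorter than one window; "
                      "returning empty WindowSet", stacklevel=2)
        return WindowSet(np.empty((0, x.signal.shape[0], win_len)), np.empty(0, dtype=np.int8),
                         np.empty(0, dtype=object), np.empty(0), role)
    stride_s = 1 if role == "train" else 2
    starts = []
    for t0 in range(0, total_s, stride_s):
        if t0 + WINDOW_SECONDS > total_s or t0 + 1 >= len(consensus):
            break
        starts.append(t0)
    windows = np.stack([x.signal[:, int(t0 * x.fs):int(t0 * x.fs) + win_len]
                        for t0 in starts]) if starts else \
        np.empty((0, x.signal.shape[0], win_len))
    labels = np.array([consensus[t0 + 1] for t0 in starts], dtype=np.int8)
    sids = np.array([x.subject_id] * len(starts), dtype=object)
    return WindowSet(windows, labels, sids, np.array(starts, dtype=float), role)


def stft_logmag(w: WindowSet) -> SpectrogramBatch:
    """Per-channel centered STFT (Hann, Nfft=64, hop=16) -> ln(|S| + eps)."""
    n, c, t = w.windows.shape
    if t != int(WINDOW_SECONDS * TARGET_FS):
        raise ValueError(f"windows must have {int(WINDOW_SECONDS * TARGET_FS)} samples, got {t}")
    if n == 0:
        return SpectrogramBatch(np.empty((0, c, N_FREQ_BINS, N_TIME_FRAMES)))
    flat = w.windows.reshape(n * c, t)
    _, _, zxx = sps.stft(flat, fs=TARGET_FS, window="hann", nperseg=N_FFT,
                         noverlap=N_FFT - HOP, nfft=N_FFT, boundary="zeros",
                         padded=True, axis=-1)
    logmag = np.log(np.abs(zxx) + LOG_FLOOR)
    return SpectrogramBatch(logmag.reshape(n, c, N_FREQ_BINS, N_TIME_FRAMES))


def stft_freq_axis() -> np.ndarray:
    """Bin-centre frequencies (Hz) of the configured STFT."""
    return np.fft.rfftfreq(N_FFT, d=1.0 / TARGET_FS)


def fit_zscore(s: SpectrogramBatch, subject_ids: np.ndarray) -> NormStats:
    """One global (mean, std) over all training spectrogram bins."""
    std = float(s.tensor.std())
    if std < 1e-12:
        raise ValueError("degenerate statistics: zero-variance spectrogram batch")
    return NormStats(mean=float(s.tensor.mean()), std=std,
                     fitted_subject_ids=tuple(sorted(set(map(str, subject_ids)))))


def apply_zscore(s: SpectrogramBatch, stats: NormStats,
                 subject_ids: np.ndarray | None = None,
                 role: str = "train") -> SpectrogramBatch:
    """Normalize with train statistics; guards eval-time subject leakage."""
    if role == "eval" and subject_ids is not None:
        overlap = set(map(str, subject_ids)) & set(stats.fitted_subject_ids)
        if overlap:
            raise LeakageError("normalization statistics were fitted on eval subjects: "
                               f"{sorted(overlap)}")
    return SpectrogramBatch((s.tensor - stats.mean) / stats.std, normalized=True)


# -- window archive I/O ---------------------------------------------------------

def save_window_archive(path, w: WindowSet, stats: NormStats | None = None) -> None:
    """One array file + JSON manifest, as produced by the preprocess CLI."""
    import os

    os.makedirs(path, exist_ok=True)
    np.save(os.path.join(path, "windows.npy"), w.windows.astype(np.float32))
    manifest = {
        "labels": w.labels.tolist(),
        "subject_ids": [str(s) for s in w.subject_ids],
        "start_times_s": w.start_times_s.tolist(),
        "split_role": w.split_role,
        "norm_stats": stats.to_dict() if stats is not None else None,
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh)


def load_window_archive(path) -> tuple[WindowSet, NormStats | None]:
    import os

    windows = np.load(os.path.join(path, "windows.npy"))
    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    w = WindowSet(windows=windows.astype(np.float64),
                  labels=np.array(manifest["labels"], dtype=np.int8),
                  subject_ids=np.array(manifest["subject_ids"], dtype=object),
                  start_times_s=np.array(manifest["start_times_s"], dtype=float),
                  split_role=manifest["split_role"])
    stats = (NormStats.from_dict(manifest["norm_stats"])
             if manifest.get("norm_stats") else None)
    return w, stats
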