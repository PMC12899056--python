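"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 10-20 electrode labels carried by every recording, in canonical order.
ELECTRODES: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)


@dataclass
class EEGRecording:
    """One subject's multichannel EEG plus expert annotations.

    ``signal`` is electrodes x samples in microvolts, ordered as
    :data:`ELECTRODES`. ``annotations`` is a 3 x T_seconds binary matrix
    (one row per expert). ``truth_mask`` is only present for synthetic data.
    """

    subject_id: str
    signal: np.ndarray
    fs: float
    annotations: np.ndarray | None = None
    truth_mask: np.ndarray | None = None
    electrode_names: tuple[str, ...] = field(default=ELECTRODES)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (electrodes x samples)")
        if self.annotations is not None:
            self.annotations = np.asarray(self.annotations, dtype=np.int8)
            if self.annotations.shape[0] != 3:
                raise ValueError("annotations must have exactly 3 expert rows")
            if not np.isin(self.annotations, (0, 1)).all():
                raise ValueError("annotations must be binary")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask, dtype=np.int8)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_seconds(self) -> int:
        """Whole annotated seconds covered by the signal."""
        return int(self.signal.shape[1] // self.fs)
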