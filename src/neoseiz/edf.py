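"""Minimal European Data Format (EDF) reader/writer.

Supports the subset this package needs: continuous 16-bit recordings, one
fixed sampling rate for all channels, 1-second data records. Physical
values are microvolts.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_edf", "read_edf"]

_HDR = 256  # bytes in the fixed header and per-signal header block


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, signal: np.ndarray, fs: float, labels: list[str],
              patient_id: str = "X", recording_id: str = "synthetic") -> None:
    """Write ``signal`` (channels x samples, microvolts) as 16-bit EDF."""
    signal = np.asarray(signal, dtype=np.float64)
    nch, nsamp = signal.shape
    if len(labels) != nch:
        raise ValueError("one label per channel required")
    if fs != int(fs):
        raise ValueError("integer sampling rates only")
    spr = int(fs)  # samples per 1-s record
    n_records = nsamp // spr
    if n_records < 1:
        raise ValueError("signal shorter than one 1-s data record")
    signal = signal[:, : n_records * spr]

    # symmetric physical range per channel; digital range fixed at int16
    phys_max = np.maximum(np.abs(signal).max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field(patient_id, 80))
        fh.write(_field(recording_id, 80))
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(_HDR + nch * _HDR, 8))
        fh.write(_field("", 44))
        fh.write(_field(n_records, 8))
        fh.write(_field("1", 8))
        fh.write(_field(nch, 4))
        for lab in labels:
            fh.write(_field(lab, 16))
        fh.write(b" " * 80 * nch)                       # transducer
        for _ in range(nch):
            fh.write(_field("uV", 8))
        for pm in phys_max:
            fh.write(_field(f"{-pm:.3f}"[:8], 8))
        for pm in phys_max:
            fh.write(_field(f"{pm:.3f}"[:8], 8))
        for _ in range(nch):
            fh.write(_field(dig_min, 8))
        for _ in range(nch):
            fh.write(_field(dig_max, 8))
        fh.write(b" " * 80 * nch)                       # prefiltering
        for _ in range(nch):
            fh.write(_field(spr, 8))
        fh.write(b" " * 32 * nch)                       # reserved
        scale = (dig_max - dig_min) / (2.0 * phys_max)  # digital per physical
        digital = np.clip(np.round(signal * scale[:, None]), dig_min, dig_max).astype("<i2")
        # record-interleaved layout: for each second, all channels
        rec = digital.reshape(nch, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec).tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file written by :func:`write_edf` (uniform rate, 1-s records)."""
    with open(path, "rb") as fh:
        header = fh.read(_HDR)
        n_records = int(header[236:244])
        record_dur = float(header[244:252])
        nch = int(header[252:256])
        sig_hdr = fh.read(nch * _HDR)

        def col(offset: int, width: int):
            base = offset * nch
            return [sig_hdr[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                    for i in range(nch)]

        # per-signal header fields are stored column-major by field
        pos = 0
        fields = {}
        for name, width in (("label", 16), ("transducer", 80), ("dim", 8),
                            ("phys_min", 8), ("phys_max", 8), ("dig_min", 8),
                            ("dig_max", 8), ("prefilter", 80), ("spr", 8),
                            ("reserved", 32)):
            fields[name] = [sig_hdr[pos + i * width: pos + (i + 1) * width]
                            .decode("ascii").strip() for i in range(nch)]
            pos += width * nch

        labels = fields["label"]
        spr = [int(s) for s in fields["spr"]]
        if len(set(spr)) != 1:
            raise ValueError("mixed sampling rates are not supported")
        phys_min = np.array([float(v) for v in fields["phys_min"]])
        phys_max = np.array([float(v) for v in fields["phys_max"]])
        dig_min = np.array([float(v) for v in fields["dig_min"]])
        dig_max = np.array([float(v) for v in fields["dig_max"]])

        raw = np.frombuffer(fh.read(n_records * nch * spr[0] * 2), dtype="<i2")
    rec = raw.reshape(n_records, nch, spr[0]).transpose(1, 0, 2).reshape(nch, -1)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    signal = (rec - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    fs = spr[0] / record_dur
    return signal, fs, labels
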