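"""EDF (European Data Format) input/output.

Reading goes through MNE's EDF reader and returns microvolt arrays.
Writing uses a minimal EDF implementation sufficient for round-tripping
synthetic cohorts: fixed-length 1-s data records of little-endian 16-bit
integers with per-channel physical scaling.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import EEGRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def read_edf(
    path: str | Path,
    channels: Sequence[str] | None = None,
    subject_id: int = -1,
    session_id: int = -1,
    kss: int = 0,
) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolt units).

    ``channels`` selects and orders channels; ``None`` keeps the stored
    order.  Subject/session identity and the KSS rating are not part of
    EDF proper and are supplied by the caller (typically from a cohort
    manifest).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rates = {raw.info["sfreq"]}
    if len(rates) != 1:
        raise ValueError(f"inconsistent sampling rates in {path}: {sorted(rates)}")
    if channels is not None:
        missing = [c for c in channels if c not in raw.ch_names]
        if missing:
            raise KeyError(
                f"channel(s) {missing} absent from {path.name}; available: {raw.ch_names}"
            )
        raw = raw.reorder_channels(list(channels)).pick(list(channels))
    data = raw.get_data() * 1e6  # MNE returns volts for EEG channels
    return EEGRecording(
        subject_id=subject_id,
        session_id=session_id,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        samples=data,
        kss=kss,
    )


def _field(value, width: int) -> bytes:
    b = str(value).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _phys_bounds(x: np.ndarray) -> tuple[float, float]:
    """Symmetric physical range, written back exactly as the 8-char header field."""
    m = max(1e-6, float(np.abs(x).max()) * 1.0000001)
    s = f"{m:.6g}"[:8]
    m = float(s)
    return -m, m


def write_edf(
    path: str | Path,
    data: np.ndarray,
    sampling_rate: float,
    channel_names: Sequence[str],
    subject: str = "X",
    recording: str = "synthetic",
) -> Path:
    """Write an (n_channels, n_samples) microvolt array as a minimal EDF.

    Uses 1-s records; a trailing partial second is dropped (EDF records
    are fixed-length).  Quantization is 16-bit over a symmetric
    per-channel physical range.
    """
    data = np.atleast_2d(np.asarray(data, float))
    n_ch, n = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length must match data rows")
    spr = int(round(sampling_rate))
    if abs(spr - sampling_rate) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate")
    n_rec = n // spr
    if n_rec == 0:
        raise ValueError("signal shorter than one 1-s EDF record")

    bounds = [_phys_bounds(data[c]) for c in range(n_ch)]
    hdr = b""
    hdr += _field("0", 8)
    hdr += _field(subject, 80)
    hdr += _field(recording, 80)
    hdr += _field("01.01.20", 8) + _field("00.00.00", 8)
    hdr += _field(256 * (n_ch + 1), 8)
    hdr += _field("", 44)
    hdr += _field(n_rec, 8)
    hdr += _field(1, 8)  # record duration, s
    hdr += _field(n_ch, 4)
    hdr += b"".join(_field(name, 16) for name in channel_names)
    hdr += b"".join(_field("EEG", 80) for _ in range(n_ch))
    hdr += b"".join(_field("uV", 8) for _ in range(n_ch))
    hdr += b"".join(_field(f"{lo:.6g}"[:8], 8) for lo, _ in bounds)
    hdr += b"".join(_field(f"{hi:.6g}"[:8], 8) for _, hi in bounds)
    hdr += b"".join(_field(_DIG_MIN, 8) for _ in range(n_ch))
    hdr += b"".join(_field(_DIG_MAX, 8) for _ in range(n_ch))
    hdr += b"".join(_field("", 80) for _ in range(n_ch))
    hdr += b"".join(_field(spr, 8) for _ in range(n_ch))
    hdr += b"".join(_field("", 32) for _ in range(n_ch))

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                lo, hi = bounds[c]
                chunk = data[c, r * spr : (r + 1) * spr]
                dig = np.round(
                    (chunk - lo) / (hi - lo) * (_DIG_MAX - _DIG_MIN) + _DIG_MIN
                )
                fh.write(np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2").tobytes())
    return path
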