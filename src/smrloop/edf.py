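"""EDF (European Data Format) reading and writing plus event sidecars.

Signals travel as 16-bit EDF with per-channel physical scaling; events
live in a tab-separated sidecar (``<name>.events.tsv`` with columns
``onset_sample`` and ``label``) next to the EDF file, since EDF
annotation support varies across tools. Reading is delegated to MNE;
the writer emits plain classic EDF.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .recordings import EEGRecording, SEPRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fmt(value: float, width: int = 8) -> bytes:
    """Format a number into a fixed-width ASCII EDF header field."""
    for fmt in (f"{value:.6g}", f"{value:.4g}", f"{value:.2g}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} into {width} chars")


def _record_duration(n_samples: int, sampling_rate: float) -> float:
    """Pick a record duration that tiles the signal exactly."""
    for dur in (1.0, 0.5, 0.25, 0.2, 0.1, 0.05, 0.02, 0.01):
        spr = dur * sampling_rate
        if spr == int(spr) and n_samples % int(spr) == 0 and int(spr) > 0:
            return dur
    return 0.0


def write_edf(
    path: str | Path,
    signal: np.ndarray,
    sampling_rate: float,
    channel_labels: list[str],
    physical_dim: str = "uV",
) -> Path:
    """Write a channels x samples array as a classic 16-bit EDF file.

    Each channel gets its own physical min/max (full 16-bit dynamic
    range). If no record duration tiles the signal exactly, the tail is
    zero-padded to a whole record with a warning.
    """
    path = Path(path)
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n_ch, n_samples = signal.shape
    if len(channel_labels) != n_ch:
        raise ValueError("channel label count mismatch")

    dur = _record_duration(n_samples, sampling_rate)
    if dur == 0.0:
        dur = 1.0
        spr = int(round(sampling_rate))
        pad = (-n_samples) % spr
        warnings.warn(
            f"padding {pad} zero samples to complete the last EDF record",
            stacklevel=2,
        )
        signal = np.pad(signal, ((0, 0), (0, pad)))
        n_samples = signal.shape[1]
    spr = int(round(dur * sampling_rate))
    n_records = n_samples // spr

    phys_min = signal.min(axis=1)
    phys_max = signal.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round(
        (signal - phys_min[:, None]) / gain[:, None] + _DIG_MIN
    ).astype("<i2")

    header = bytearray()
    header += b"0".ljust(8)
    header += b"X".ljust(80)                       # patient id
    header += b"smrloop synthetic".ljust(80)       # recording id
    header += b"01.01.00" + b"00.00.00"
    header += str(256 * (n_ch + 1)).ljust(8).encode()
    header += b" " * 44
    header += str(n_records).ljust(8).encode()
    header += _fmt(dur)
    header += str(n_ch).ljust(4).encode()
    for label in channel_labels:
        header += label[:16].ljust(16).encode()
    header += b" " * 80 * n_ch                     # transducer
    header += physical_dim[:8].ljust(8).encode() * n_ch
    for v in phys_min:
        header += _fmt(v)
    for v in phys_max:
        header += _fmt(v)
    header += str(_DIG_MIN).ljust(8).encode() * n_ch
    header += str(_DIG_MAX).ljust(8).encode() * n_ch
    header += b" " * 80 * n_ch                     # prefiltering
    header += str(spr).ljust(8).encode() * n_ch
    header += b" " * 32 * n_ch

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # data records: per record, all samples of ch1, then ch2, ...
        for rec in range(n_records):
            chunk = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(chunk.tobytes())
    return path


def events_path(edf_path: str | Path) -> Path:
    p = Path(edf_path)
    return p.with_name(p.stem + ".events.tsv")


def write_events(edf_path: str | Path, events: pd.DataFrame) -> Path:
    out = events_path(edf_path)
    events.to_csv(out, sep="\t", index=False)
    return out


def write_recording(path: str | Path, recording) -> Path:
    """Write an EEG or SEP recording as EDF plus an event sidecar."""
    path = Path(path)
    if isinstance(recording, SEPRecording):
        write_edf(path, recording.traces, recording.sampling_rate,
                  recording.montage_labels)
        events = pd.DataFrame({
            "onset_sample": recording.stim_onsets, "label": "stim",
        })
    else:
        write_edf(path, recording.signal, recording.sampling_rate,
                  recording.channel_labels)
        events = recording.events
    write_events(path, events)
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file (via MNE) plus its event sidecar, if present.

    Signals come back in microvolts. A missing sidecar yields an empty
    event table with a warning.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:   # noqa: BLE001 - surface a parse error
        size = path.stat().st_size
        raise ValueError(
            f"cannot parse {path} as EDF (file size {size} bytes): {exc}"
        ) from exc
    signal = raw.get_data() * 1e6      # MNE returns SI volts
    ev = events_path(path)
    if ev.exists():
        events = pd.read_csv(ev, sep="\t")
    else:
        warnings.warn(f"no event sidecar at {ev}; empty event list",
                      stacklevel=2)
        events = pd.DataFrame(columns=["onset_sample", "label"])
    return EEGRecording(
        signal=signal,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
    )


def as_sep_recording(recording: EEGRecording) -> SEPRecording:
    """Reinterpret a generic recording as a SEP session.

    Channel labels become montage labels and events labelled ``stim``
    become stimulus onsets.
    """
    stim = recording.events.query("label == 'stim'")["onset_sample"]
    if stim.empty:
        raise ValueError("no 'stim' events in the recording")
    return SEPRecording(
        traces=recording.signal,
        sampling_rate=recording.sampling_rate,
        montage_labels=list(recording.channel_labels),
        stim_onsets=stim.to_numpy(),
    )
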