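"""Somatosensory-evoked-potential (SEP) quantification.

Median-nerve SEPs are quantified per component on its standard bipolar
montage: N9 (brachial plexus) on EPi-EPc, N13 (cervical spinal cord) on
C2S-Fz and N20 (earliest primary somatosensory cortex response) on
CPc-Fz. The chain is: 3-500 Hz zero-phase band-limiting, 600-ms epochs
centered on each stimulus onset, across-epoch averaging, z-scoring of
the average against its own pre-stimulus window, and an extrema search
within +-3 ms of each component's nominal latency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .recordings import SEPRecording

logger = logging.getLogger(__name__)

#: (montage, nominal latency ms) per component
COMPONENT_MONTAGES = {
    "N9": ("EPi-EPc", 9.0),
    "N13": ("C2S-Fz", 13.0),
    "N20": ("CPc-Fz", 20.0),
}

EPOCH_HALF_MS = 300.0   # epochs span -300..+300 ms around the stimulus


@dataclass
class SEPComponent:
    name: str
    montage: str
    latency_ms: float
    amplitude_z: float   # z-units; negative for N components
    n_epochs: int


def filter_sep(
    recording: SEPRecording,
    highpass: float = 3.0,
    lowpass: float = 500.0,
    order: int = 4,
) -> SEPRecording:
    """Zero-phase 3-500 Hz band-limiting of all montage traces."""
    if recording.sampling_rate <= 2 * lowpass:
        raise ValueError("sampling rate too low for the requested low-pass")
    b_hp, a_hp = butter(order, highpass, btype="highpass",
                        fs=recording.sampling_rate)
    b_lp, a_lp = butter(order, lowpass, btype="lowpass",
                        fs=recording.sampling_rate)
    traces = filtfilt(b_lp, a_lp, filtfilt(b_hp, a_hp, recording.traces,
                                           axis=1), axis=1)
    return replace(recording, traces=traces)


def epoch_sep(recording: SEPRecording) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus-centered 600-ms epochs.

    Returns ``(epochs, times_ms)`` where ``epochs`` has shape
    (n_montages, n_epochs, n_samples) and ``times_ms`` runs from -300 to
    just under +300 ms with the stimulus at the center sample. Onsets
    without a full window on both sides are dropped with a log entry.
    """
    fs = recording.sampling_rate
    half = round(EPOCH_HALF_MS / 1000.0 * fs)
    usable = [
        int(o) for o in recording.stim_onsets
        if o - half >= 0 and o + half <= recording.n_samples
    ]
    dropped = len(recording.stim_onsets) - len(usable)
    if dropped:
        logger.info("dropped %d onsets without a full +-300 ms window",
                    dropped)
    if not usable:
        raise ValueError("no stimulus onset has a full epoch window")
    epochs = np.stack(
        [recording.traces[:, o - half:o + half] for o in usable], axis=1
    )
    times_ms = (np.arange(2 * half) - half) / fs * 1000.0
    return epochs, times_ms


def zscore_average(
    epochs: np.ndarray, times_ms: np.ndarray
) -> np.ndarray:
    """Average epochs, then z-score against the pre-stimulus window.

    The mean and SD are taken from the -300..0 ms segment of the
    *averaged* trace (z-scoring follows averaging). Output shape matches
    the montage x samples layout of a single epoch.
    """
    pre = times_ms < 0.0
    if pre.sum() < 2:
        raise ValueError("need >= 2 pre-stimulus samples")
    avg = np.asarray(epochs, dtype=float).mean(axis=-2)
    mu = avg[..., pre].mean(axis=-1, keepdims=True)
    sd = avg[..., pre].std(axis=-1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero pre-stimulus standard deviation "
                         "(degenerate input)")
    return (avg - mu) / sd


def find_component(
    z_waveform: np.ndarray,
    times_ms: np.ndarray,
    nominal_latency_ms: float,
    search_ms: float = 3.0,
    polarity: str = "negative",
) -> tuple[float, float]:
    """Extremum within +-``search_ms`` of the nominal latency.

    For negative components the most negative value wins; equal extrema
    break to the earlier latency (argmin/argmax return the first hit).
    Returns ``(latency_ms, amplitude_z)``.
    """
    window = (times_ms >= nominal_latency_ms - search_ms) & (
        times_ms <= nominal_latency_ms + search_ms
    )
    if not window.any():
        raise ValueError("search window outside the epoch")
    seg = np.asarray(z_waveform, dtype=float)[window]
    i = int(np.argmin(seg)) if polarity == "negative" else int(np.argmax(seg))
    return float(times_ms[window][i]), float(seg[i])


def extract_all(
    recording: SEPRecording,
    components: dict[str, tuple[str, float]] = COMPONENT_MONTAGES,
    prefiltered: bool = False,
) -> list[SEPComponent]:
    """Quantify all SEP components present in the recording.

    Filters, epochs, averages/z-scores each montage, then searches each
    component on its montage. Components whose montage is absent are
    skipped with a warning (partial output).
    """
    rec = recording if prefiltered else filter_sep(recording)
    epochs, times_ms = epoch_sep(rec)
    z = zscore_average(epochs, times_ms)
    n_epochs = epochs.shape[1]

    out: list[SEPComponent] = []
    for name, (montage, nominal) in components.items():
        if montage not in rec.montage_labels:
            warnings.warn(
                f"montage {montage!r} for {name} missing; component skipped",
                stacklevel=2,
            )
            continue
        row = rec.montage_labels.index(montage)
        latency, amplitude = find_component(z[row], times_ms, nominal)
        out.append(SEPComponent(name, montage, latency, amplitude, n_epochs))
    if not out:
        raise ValueError("no component montage present in the recording")
    return out


def components_table(components: list[SEPComponent]) -> pd.DataFrame:
    """Tidy table (component, montage, latency_ms, amplitude_z, n_epochs)."""
    return pd.DataFrame(
        [(c.name, c.montage, c.latency_ms, c.amplitude_z, c.n_epochs)
         for c in components],
        columns=["component", "montage", "latency_ms", "amplitude_z",
                 "n_epochs"],
    )
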