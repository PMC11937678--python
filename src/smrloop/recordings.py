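"""In-memory containers for continuous EEG and SEP recordings.

Signals are stored as ``channels x samples`` float arrays in microvolts.
Events are kept as a plain :class:`pandas.DataFrame` with ``onset_sample``
(0-based) and ``label`` columns so they serialize naturally to
delimiter-separated sidecar files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical trial-period labels, in within-trial order
TRIAL_LABELS = ("rest", "ready", "task", "blank")


@dataclass
class EEGRecording:
    """Continuous multichannel EEG with a trial-period event table.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sampling_rate : float
        Sampling rate in Hz.
    channel_labels : list of str
        Extended 10-20 channel names, one per signal row.
    events : pandas.DataFrame
        Columns ``onset_sample`` (int) and ``label`` (one of
        ``rest``/``ready``/``task``/``blank``), sorted by onset.
    """

    signal: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["onset_sample", "label"])
    )

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(self.events):
            onsets = self.events["onset_sample"].to_numpy()
            if onsets.min() < 0 or onsets.max() >= self.n_samples:
                raise ValueError("event onsets outside record length")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D trace of a named channel (microvolts)."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording "
                           f"(have {self.channel_labels})") from None
        return self.signal[idx]

    def trials(self) -> list[dict[str, int]]:
        """Group events into trials.

        Returns one dict per trial mapping period label to onset sample.
        A trial starts at each ``rest`` event and collects the following
        ``ready``/``task``/``blank`` onsets.
        """
        out: list[dict[str, int]] = []
        current: dict[str, int] | None = None
        for onset, label in self.events[["onset_sample", "label"]].itertuples(
            index=False
        ):
            if label == "rest":
                current = {"rest": int(onset)}
                out.append(current)
            elif current is not None:
                current[label] = int(onset)
        return out


@dataclass
class SEPRecording:
    """Somatosensory-evoked-potential recording.

    ``traces`` holds one row per montage (bipolar derivation already
    applied, e.g. ``CPc-Fz``); ``stim_onsets`` are 0-based sample indices
    of stimulus delivery.
    """

    traces: np.ndarray
    sampling_rate: float
    montage_labels: list[str]
    stim_onsets: np.ndarray

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.stim_onsets = np.asarray(self.stim_onsets, dtype=int)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (montages x samples)")
        if len(self.montage_labels) != self.traces.shape[0]:
            raise ValueError("montage label count mismatch")
        if np.any(np.diff(self.stim_onsets) <= 0):
            raise ValueError("stimulus onsets must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    def montage(self, label: str) -> np.ndarray:
        try:
            idx = self.montage_labels.index(label)
        except ValueError:
            raise KeyError(f"montage {label!r} not in recording "
                           f"(have {self.montage_labels})") from None
        return self.traces[idx]
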