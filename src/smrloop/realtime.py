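"""Closed-loop sensorimotor-rhythm (SMR) feedback pipeline, replayed offline.

The online chain mirrors a real-time EEG neurofeedback system: every
100 ms the latest 5 s of the large-Laplacian C3 signal are band-pass
(3-70 Hz, third-order Butterworth) and notch (50 Hz) filtered with
zero-phase (forward-backward) application; the final 1 s is
Hanning-windowed and Fourier transformed to give band power at 1-Hz
resolution; the event-related spectral perturbation (ERSP)

    ERSP(f, t) = 100 * (Power(f, t) - Reference(f)) / Reference(f)

is computed against the average power of the current trial's rest
period; the SMR value (alpha-band mean, or the calibrated
frequency-of-interest bin) is smoothed over the latest 10 samples and
mapped linearly onto a 20-frame virtual finger: the 25th percentile of
the calibration distribution (strong desynchronization) shows the fully
abducted finger (frame 20), the 75th percentile frame 1.

All replay computations are strictly causal: a tick at time t sees only
samples up to t.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, get_window

from .recordings import EEGRecording
from .synth import DEFAULT_NEIGHBORS

logger = logging.getLogger(__name__)

ALPHA_BAND = (8, 13)


# ---------------------------------------------------------------------------
# spatial and temporal filtering
# ---------------------------------------------------------------------------

def large_laplacian(
    recording: EEGRecording,
    center: str = "C3",
    neighbors: tuple[str, ...] = DEFAULT_NEIGHBORS,
) -> np.ndarray:
    """Large-Laplacian spatial filter: center minus the neighbor mean."""
    missing = [
        ch for ch in (center, *neighbors) if ch not in recording.channel_labels
    ]
    if missing:
        raise KeyError(f"recording is missing channel(s) {missing}")
    out = recording.channel(center).astype(float).copy()
    out -= np.mean([recording.channel(ch) for ch in neighbors], axis=0)
    return out


def _replay_filters(sampling_rate: float, band=(3.0, 70.0),
                    notch=50.0, order=3, notch_halfwidth=2.0):
    bp = butter(order, band, btype="bandpass", fs=sampling_rate)
    bs = butter(order, (notch - notch_halfwidth, notch + notch_halfwidth),
                btype="bandstop", fs=sampling_rate)
    return bp, bs


def buffer_filter(
    buffer: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (3.0, 70.0),
    notch: float = 50.0,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase band-pass + notch filtering of one analysis buffer.

    Forward-backward application (``filtfilt``) doubles the effective
    order and cancels phase delay, as the online system did on each 5-s
    buffer.
    """
    buffer = np.asarray(buffer, dtype=float)
    (b_bp, a_bp), (b_bs, a_bs) = _replay_filters(
        sampling_rate, band, notch, order
    )
    padlen = 3 * max(len(a_bp), len(b_bp), len(a_bs), len(b_bs))
    if buffer.size <= padlen:
        raise ValueError(
            f"buffer of {buffer.size} samples is too short for zero-phase "
            f"filtering (needs > {padlen})"
        )
    out = filtfilt(b_bp, a_bp, buffer)
    return filtfilt(b_bs, a_bs, out)


# ---------------------------------------------------------------------------
# spectral estimation and ERSP
# ---------------------------------------------------------------------------

@dataclass
class OnlinePowerSample:
    """Band power of the latest 1-s window at one update tick."""

    tick_time: float
    freqs: np.ndarray      # integer-Hz bins (1-s window -> 1 Hz resolution)
    power: np.ndarray      # uV^2/Hz, >= 0


def stft_power(
    filtered_buffer: np.ndarray,
    sampling_rate: float,
    tick: float = 0.0,
    window_s: float = 1.0,
) -> OnlinePowerSample:
    """Hanning-windowed periodogram of the final second of a buffer."""
    n_win = round(window_s * sampling_rate)
    if filtered_buffer.size < n_win:
        raise ValueError("buffer must cover at least one analysis window")
    x = np.asarray(filtered_buffer[-n_win:], dtype=float)
    win = get_window("hann", n_win)
    spec = np.fft.rfft(x * win)
    # one-sided density normalization (matches scipy periodogram)
    power = (np.abs(spec) ** 2) * (2.0 / (sampling_rate * np.sum(win ** 2)))
    power[0] /= 2.0
    if n_win % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n_win, d=1.0 / sampling_rate)
    return OnlinePowerSample(tick_time=tick, freqs=freqs, power=power)


def compute_reference(power_samples: list[np.ndarray]) -> np.ndarray:
    """Per-bin mean power over the rest-period ticks of one trial."""
    if not power_samples:
        raise ValueError("no rest-period power samples to average")
    return np.mean(np.asarray(power_samples, dtype=float), axis=0)


def ersp(power: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Percent spectral-power change relative to the rest reference."""
    power = np.asarray(power, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference power must be positive in every bin")
    return 100.0 * (power - reference) / reference


def smr_alpha(
    ersp_bins: np.ndarray,
    freqs: np.ndarray,
    mode: str = "band",
    foi: float | None = None,
    band: tuple[int, int] = ALPHA_BAND,
) -> float:
    """Scalar SMR value from per-bin ERSP.

    ``mode="band"`` averages the alpha band (8-13 Hz inclusive);
    ``mode="foi"`` returns the single calibrated frequency-of-interest
    bin.
    """
    freqs = np.asarray(freqs)
    if mode == "band":
        mask = (freqs >= band[0]) & (freqs <= band[1])
        if not mask.any():
            raise ValueError("no bins inside the alpha band")
        return float(np.mean(np.asarray(ersp_bins)[mask]))
    if mode == "foi":
        if foi is None:
            raise ValueError("FOI mode requires a calibrated frequency")
        idx = int(np.argmin(np.abs(freqs - foi)))
        if abs(freqs[idx] - foi) > 0.5:
            raise ValueError(f"no frequency bin near FOI {foi} Hz")
        return float(np.asarray(ersp_bins)[idx])
    raise ValueError(f"unknown SMR mode {mode!r}")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class FeedbackCalibration:
    """Per-participant mapping from SMR values to feedback frames."""

    foi: float                 # frequency of interest, Hz, in [8, 13]
    p25: float                 # percent-ERSP percentiles of the open-loop
    p75: float                 # calibration block
    n_frames: int = 20
    smr_mode: str = "foi"      # "foi" or "band"

    def __post_init__(self) -> None:
        if self.p25 > self.p75:
            raise ValueError("p25 must not exceed p75")


def calibrate_foi(
    ersp_map,
    task_window: tuple[float, float] = (6.0, 12.0),
    band: tuple[int, int] = ALPHA_BAND,
) -> int:
    """Frequency of interest: deepest task-period alpha desynchronization.

    ``ersp_map`` is any object with ``freqs`` (Hz), ``times`` (trial-
    relative s) and ``values`` (freq x time percent-change matrix), e.g.
    :class:`smrloop.spectral.ERSPMap` of the open-loop block. Returns the
    integer alpha bin with the most negative trial- and task-averaged
    ERSP; ties break to the lowest frequency. If no bin is negative a
    warning is emitted and the argmin is returned regardless.
    """
    freqs = np.asarray(ersp_map.freqs)
    times = np.asarray(ersp_map.times)
    fmask = (freqs >= band[0]) & (freqs <= band[1])
    tmask = (times >= task_window[0]) & (times <= task_window[1])
    if not fmask.any() or not tmask.any():
        raise ValueError("ERSP map does not cover the alpha band / task window")
    task_mean = np.asarray(ersp_map.values)[np.ix_(fmask, tmask)].mean(axis=1)
    if task_mean.min() >= 0:
        warnings.warn(
            "no negative task-period ERSP in the alpha band; FOI set to the "
            "least positive bin",
            stacklevel=2,
        )
    # np.argmin already returns the first (lowest-frequency) minimum on ties
    return int(round(freqs[fmask][int(np.argmin(task_mean))]))


def calibrate_from_trace(
    trace: "FeedbackTrace", foi: float, n_frames: int = 20,
    smr_mode: str = "foi",
) -> FeedbackCalibration:
    """Build a feedback calibration from an open-loop replay trace.

    The 25th/75th percentiles of the smoothed SMR distribution over the
    open-loop block define the frame-mapping anchors.
    """
    values = trace.table["smoothed_smr"].dropna().to_numpy()
    if values.size == 0:
        raise ValueError("trace has no valid smoothed SMR samples")
    p25, p75 = np.percentile(values, [25.0, 75.0])
    return FeedbackCalibration(foi=foi, p25=float(p25), p75=float(p75),
                               n_frames=n_frames, smr_mode=smr_mode)


# ---------------------------------------------------------------------------
# smoothing and frame mapping
# ---------------------------------------------------------------------------

def smooth_smr(raw_smr_history, n: int = 10) -> float:
    """Mean of the most recent ``min(n, available)`` raw SMR samples."""
    history = np.asarray(raw_smr_history, dtype=float)
    if history.size == 0:
        raise ValueError("need at least one raw SMR sample")
    return float(np.mean(history[-n:]))


def map_to_frame(smoothed_smr: float, calibration: FeedbackCalibration) -> int:
    """Linear SMR -> frame-index map.

    Stronger SMR (more negative ERSP, deeper desynchronization) means a
    more abducted finger: values at or below the 25th percentile map to
    the last frame (20), values at or above the 75th percentile to frame
    1, with affine interpolation and round-half-up in between.
    """
    if calibration.p25 == calibration.p75:
        raise ValueError("degenerate calibration: p25 == p75")
    n = calibration.n_frames
    frac = (smoothed_smr - calibration.p25) / (calibration.p75 - calibration.p25)
    value = n + frac * (1 - n)
    frame = int(np.floor(value + 0.5))  # round half up
    return int(np.clip(frame, 1, n))


# ---------------------------------------------------------------------------
# full replay
# ---------------------------------------------------------------------------

@dataclass
class FeedbackTrace:
    """Per-tick output of a closed-loop replay.

    ``table`` columns: ``tick_s``, ``raw_smr``, ``smoothed_smr`` (percent
    ERSP) and ``frame`` (1..20; NaN for open-loop replays without a
    calibration).
    """

    table: pd.DataFrame
    calibration: FeedbackCalibration | None = None
    skipped_ticks: int = 0


def run_closed_loop_replay(
    recording: EEGRecording,
    calibration: FeedbackCalibration | None = None,
    center: str = "C3",
    neighbors: tuple[str, ...] = DEFAULT_NEIGHBORS,
    buffer_s: float = 5.0,
    window_s: float = 1.0,
    tick_s: float = 0.1,
    smoothing: int = 10,
    smr_mode: str | None = None,
    foi: float | None = None,
    min_ref_windows: int = 5,
) -> FeedbackTrace:
    """Causal tick-by-tick replay of the online feedback computation.

    Without a calibration the replay runs open-loop: SMR is the
    alpha-band average (unless ``smr_mode`` forces otherwise) and the
    frame column is NaN. The per-trial rest reference is accumulated
    causally: during a trial's rest period the reference is the mean of
    the rest-window power samples seen so far; from the ready period on
    it is frozen for the remainder of the trial. Ticks before the first
    full buffer, or before any reference exists, yield NaN and are
    counted in ``skipped_ticks``. Outside the rest period, a trial whose
    reference averages fewer than ``min_ref_windows`` rest windows (the
    cold-start case: a session's very first trial only ever exposes one
    full rest window to a 5-s causal buffer) is treated as having a
    degenerate reference and yields NaN ticks with a log entry.
    """
    fs = recording.sampling_rate
    lap = large_laplacian(recording, center, neighbors)
    if smr_mode is None:
        smr_mode = calibration.smr_mode if calibration is not None else "band"
    if foi is None and calibration is not None:
        foi = calibration.foi
    if smr_mode == "foi" and foi is None:
        raise ValueError("FOI mode requires a calibration or explicit foi")

    n_buf = round(buffer_s * fs)
    n_tick = round(tick_s * fs)
    if lap.size < n_buf:
        raise ValueError("recording shorter than one analysis buffer")

    trials = recording.trials()
    rest_bounds = []
    for tr in trials:
        start = tr["rest"]
        end = tr.get("ready", start + round(5.0 * fs))
        rest_bounds.append((start, end))
    trial_starts = np.array([tr["rest"] for tr in trials])

    rows = []
    skipped = 0
    history: deque[float] = deque(maxlen=smoothing)
    ref_trial = -1
    rest_acc: list[np.ndarray] = []
    trial_reference: np.ndarray | None = None
    degenerate_logged = False

    first_tick = int(np.ceil(n_buf / n_tick))
    skipped += max(0, first_tick - 1)
    if skipped:
        logger.info("skipping %d ticks before the first full buffer", skipped)

    for k in range(first_tick, lap.size // n_tick + 1):
        end = k * n_tick
        if end > lap.size:
            break
        t = end / fs
        filtered = buffer_filter(lap[end - n_buf:end], fs)
        sample = stft_power(filtered, fs, tick=t, window_s=window_s)

        trial_idx = int(np.searchsorted(trial_starts, end, side="right")) - 1
        in_rest = False
        if trial_idx >= 0:
            if trial_idx != ref_trial:
                ref_trial = trial_idx
                rest_acc = []
                trial_reference = None
            r_start, r_end = rest_bounds[trial_idx]
            win_start = end - round(window_s * fs)
            in_rest = end <= r_end
            if win_start >= r_start and end <= r_end:
                rest_acc.append(sample.power)
                trial_reference = compute_reference(rest_acc)

        # within rest the accumulating reference may be provisional; from
        # the ready period on it must rest on enough windows to be usable
        usable = trial_reference is not None and (
            in_rest or len(rest_acc) >= min_ref_windows
        )
        if not usable:
            if (trial_reference is not None and not in_rest
                    and not degenerate_logged):
                logger.info(
                    "trial %d reference built from %d < %d rest windows; "
                    "ticks reported as NaN", trial_idx, len(rest_acc),
                    min_ref_windows,
                )
                degenerate_logged = True
            raw = np.nan
        else:
            raw = smr_alpha(
                ersp(sample.power, trial_reference), sample.freqs,
                mode=smr_mode, foi=foi,
            )
        if np.isfinite(raw):
            history.append(raw)
            smoothed = smooth_smr(list(history), smoothing)
        else:
            smoothed = np.nan
        frame = (
            map_to_frame(smoothed, calibration)
            if calibration is not None and np.isfinite(smoothed)
            else np.nan
        )
        rows.append((t, raw, smoothed, frame))

    table = pd.DataFrame(rows, columns=["tick_s", "raw_smr", "smoothed_smr",
                                        "frame"])
    return FeedbackTrace(table=table, calibration=calibration,
                         skipped_ticks=skipped)
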