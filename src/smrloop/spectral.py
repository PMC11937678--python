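"""Offline spectral analysis.

Three layers:

* Welch power spectral density estimation (front-end for
  parameterization),
* simplified spectral parameterization: the log10 PSD is modelled as an
  aperiodic 1/f component plus Gaussian periodic peaks,

      log10 PSD(f) = offset - exponent * log10(f) + sum_k G_k(f),
      G_k(f) = height_k * exp(-(f - cf_k)^2 / (2 sigma_k^2)),

  fitted by iterative peak extraction from the aperiodic-flattened
  spectrum followed by a joint refit — the construction behind
  individual-alpha-frequency (IAF) and aperiodic-exponent profiles,
* trial-averaged time-frequency ERSP maps using the same 1-s Hanning
  short-time Fourier transform as the online pipeline, baselined per
  trial on the rest period.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .realtime import buffer_filter, large_laplacian
from .recordings import EEGRecording
from .synth import DEFAULT_NEIGHBORS

logger = logging.getLogger(__name__)

ALPHA_BAND = (8.0, 13.0)


class NoAlphaPeakError(ValueError):
    """Raised when no periodic peak lies inside the alpha band."""


# ---------------------------------------------------------------------------
# PSD estimation
# ---------------------------------------------------------------------------

@dataclass
class PSD:
    freqs: np.ndarray
    power: np.ndarray   # uV^2/Hz


def welch_psd(
    signal: np.ndarray,
    sampling_rate: float,
    segment_s: float = 1.0,
    overlap: float = 0.5,
) -> PSD:
    """Welch-averaged periodogram (Hanning window, density scaling)."""
    signal = np.asarray(signal, dtype=float)
    nperseg = round(segment_s * sampling_rate)
    if signal.size < nperseg:
        raise ValueError("signal shorter than one Welch segment")
    freqs, power = sps.welch(
        signal, fs=sampling_rate, window="hann", nperseg=nperseg,
        noverlap=round(overlap * nperseg), scaling="density",
    )
    return PSD(freqs=freqs, power=power)


# ---------------------------------------------------------------------------
# spectral parameterization
# ---------------------------------------------------------------------------

@dataclass
class SpectralParams:
    """Aperiodic + periodic decomposition of a power spectrum.

    ``peaks`` rows are (center_frequency_Hz, height_log10power,
    bandwidth_Hz) with bandwidth = 2 * Gaussian sigma, sorted by height
    (largest first). ``height`` is measured above the aperiodic fit.
    """

    aperiodic_offset: float
    aperiodic_exponent: float
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    fit_range: tuple[float, float] = (2.0, 40.0)
    r_squared: float = np.nan
    rmse: float = np.nan

    def aperiodic(self, freqs: np.ndarray) -> np.ndarray:
        """Aperiodic component in log10 power."""
        freqs = np.asarray(freqs, dtype=float)
        return self.aperiodic_offset - self.aperiodic_exponent * np.log10(freqs)

    def model(self, freqs: np.ndarray) -> np.ndarray:
        """Full model (log10 power): aperiodic plus Gaussian peaks."""
        out = self.aperiodic(freqs)
        for cf, height, bw in self.peaks:
            sigma = bw / 2.0
            out = out + height * np.exp(
                -((np.asarray(freqs, float) - cf) ** 2) / (2 * sigma**2)
            )
        return out


def _gaussians(freqs, *params):
    out = np.zeros_like(freqs, dtype=float)
    for i in range(0, len(params), 3):
        cf, height, sigma = params[i:i + 3]
        out += height * np.exp(-((freqs - cf) ** 2) / (2 * sigma**2))
    return out


def _fit_line(log_f, y):
    slope, intercept = np.polyfit(log_f, y, 1)
    return intercept, -slope   # offset, exponent


def _robust_aperiodic(log_f, log_psd):
    """Line fit that ignores upward excursions (periodic peaks)."""
    offset, exponent = _fit_line(log_f, log_psd)
    for _ in range(2):
        resid = log_psd - (offset - exponent * log_f)
        keep = resid <= np.median(resid)
        if keep.sum() < 3:
            break
        offset, exponent = _fit_line(log_f[keep], log_psd[keep])
    return offset, exponent


def parameterize_spectrum(
    psd: PSD,
    fit_range: tuple[float, float] = (2.0, 40.0),
    max_peaks: int = 6,
    min_peak_height: float = 0.05,
    peak_threshold: float = 2.0,
    bandwidth_bounds: tuple[float, float] = (0.5, 8.0),
) -> SpectralParams:
    """Decompose a PSD into aperiodic 1/f and Gaussian periodic parts.

    Iterative extraction: fit a robust line to the log-log spectrum,
    flatten, repeatedly pick the largest residual maximum above both
    ``min_peak_height`` and ``peak_threshold`` residual SDs, seed a
    Gaussian there and subtract it; then jointly refit all Gaussians and
    finally refit the aperiodic component on the peak-subtracted
    spectrum.
    """
    mask = (psd.freqs >= fit_range[0]) & (psd.freqs <= fit_range[1])
    freqs = np.asarray(psd.freqs[mask], dtype=float)
    if freqs.size < 5 or freqs[0] <= 0:
        raise ValueError("fit range must contain >= 5 positive-frequency bins")
    power = np.asarray(psd.power[mask], dtype=float)
    if np.any(power <= 0):
        raise ValueError("non-positive power inside the fit range")
    log_f = np.log10(freqs)
    log_psd = np.log10(power)

    offset, exponent = _robust_aperiodic(log_f, log_psd)
    flat = log_psd - (offset - exponent * log_f)

    sig_lo, sig_hi = bandwidth_bounds[0] / 2.0, bandwidth_bounds[1] / 2.0
    guesses: list[tuple[float, float, float]] = []
    work = flat.copy()
    for _ in range(max_peaks):
        i = int(np.argmax(work))
        height = work[i]
        if height < max(min_peak_height, peak_threshold * np.std(work)):
            break
        # bandwidth guess from the half-height span around the maximum
        half = height / 2.0
        left = i
        while left > 0 and work[left] > half:
            left -= 1
        right = i
        while right < work.size - 1 and work[right] > half:
            right += 1
        fwhm = max(freqs[right] - freqs[left], freqs[1] - freqs[0])
        sigma = float(np.clip(fwhm / 2.355, sig_lo, sig_hi))
        guesses.append((freqs[i], height, sigma))
        work = work - height * np.exp(-((freqs - freqs[i]) ** 2) / (2 * sigma**2))

    peaks_sig: list[tuple[float, float, float]] = []
    if guesses:
        p0, lo, hi = [], [], []
        for cf, height, sigma in guesses:
            p0 += [cf, height, sigma]
            lo += [freqs[0], 0.0, sig_lo]
            hi += [freqs[-1], 2.0 * max(height, min_peak_height), sig_hi]
        try:
            popt, _ = curve_fit(
                _gaussians, freqs, flat, p0=p0, bounds=(lo, hi), maxfev=20000
            )
            peaks_sig = [tuple(popt[i:i + 3]) for i in range(0, len(popt), 3)]
        except RuntimeError:
            logger.warning("joint Gaussian refit failed; using seed guesses")
            peaks_sig = guesses

    peak_model = _gaussians(freqs, *np.ravel(peaks_sig)) if peaks_sig else 0.0
    offset, exponent = _fit_line(log_f, log_psd - peak_model)
    if exponent < 0:
        warnings.warn(
            f"negative aperiodic exponent ({exponent:.3f}); spectrum may "
            "not be physiological",
            stacklevel=2,
        )

    model = (offset - exponent * log_f) + peak_model
    resid = log_psd - model
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((log_psd - log_psd.mean()) ** 2))
    peaks = sorted(
        [(float(cf), float(h), float(2 * s)) for cf, h, s in peaks_sig],
        key=lambda p: -p[1],
    )
    return SpectralParams(
        aperiodic_offset=float(offset),
        aperiodic_exponent=float(exponent),
        peaks=peaks,
        fit_range=fit_range,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        rmse=float(np.sqrt(ss_res / freqs.size)),
    )


def find_iaf(params: SpectralParams, band=ALPHA_BAND) -> float:
    """Individual alpha frequency: highest modelled peak inside 8-13 Hz."""
    in_band = [p for p in params.peaks if band[0] <= p[0] <= band[1]]
    if not in_band:
        raise NoAlphaPeakError(
            f"no periodic peak inside {band[0]}-{band[1]} Hz"
        )
    return max(in_band, key=lambda p: p[1])[0]


def peak_height_at_iaf(params: SpectralParams, band=ALPHA_BAND) -> float:
    """Modelled Gaussian height (log10 power) above the aperiodic fit."""
    iaf = find_iaf(params, band)   # raises NoAlphaPeakError when absent
    return max(
        (p for p in params.peaks if p[0] == iaf), key=lambda p: p[1]
    )[1]


# ---------------------------------------------------------------------------
# time-frequency ERSP maps
# ---------------------------------------------------------------------------

@dataclass
class ERSPMap:
    """Trial-averaged percent spectral-power change, frequency x time.

    ``times`` are trial-relative seconds (window end times); the
    baseline is the per-trial rest period, so map values are >= -100 and
    average ~0 over the baseline window.
    """

    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray          # freq x time, percent
    n_trials: int = 0
    baseline_window: tuple[float, float] = (1.0, 5.0)
    trial_values: np.ndarray | None = None   # trial x freq x time


def ersp_timefreq_map(
    recording: EEGRecording,
    center: str = "C3",
    neighbors: tuple[str, ...] = DEFAULT_NEIGHBORS,
    freq_range: tuple[float, float] = (1.0, 40.0),
    baseline: tuple[float, float] = (1.0, 5.0),
    window_s: float = 1.0,
    tick_s: float = 0.1,
    keep_trials: bool = False,
    signal: np.ndarray | None = None,
) -> ERSPMap:
    """Time-frequency ERSP of a motor-imagery session.

    Uses the identical 1-s Hanning STFT as the online pipeline at 1 Hz x
    ``tick_s`` resolution; the whole record is zero-phase filtered once
    (the offline equivalent of per-buffer forward-backward filtering).
    Each trial is normalized by its own rest-period mean power before
    averaging. Pass ``signal`` to analyze a pre-extracted regional time
    series (e.g. a source-space M1/S1 trace) instead of the Laplacian
    channel. Trials whose rest period yields no complete STFT window are
    excluded with a log entry.
    """
    fs = recording.sampling_rate
    x = (
        np.asarray(signal, dtype=float)
        if signal is not None
        else large_laplacian(recording, center, neighbors)
    )
    x = buffer_filter(x, fs)

    n_win = round(window_s * fs)
    hop = round(tick_s * fs)
    freqs, _, spec = sps.spectrogram(
        x, fs=fs, window="hann", nperseg=n_win, noverlap=n_win - hop,
        scaling="density", mode="psd", detrend=False,
    )
    # window j covers samples [j*hop, j*hop + n_win); its "tick time" is
    # the window end
    n_windows = spec.shape[1]
    win_start = np.arange(n_windows) * hop

    fmask = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    freqs = freqs[fmask]
    spec = spec[fmask]

    trials = recording.trials()
    trial_len = None
    if len(trials) >= 2:
        trial_len = trials[1]["rest"] - trials[0]["rest"]
    else:
        trial_len = recording.n_samples - trials[0]["rest"]
    rel_ticks = np.arange(
        round(window_s / tick_s), trial_len // hop + 1
    ) * tick_s
    n_ticks = rel_ticks.size

    per_trial = []
    for tr in trials:
        start = tr["rest"]
        # window index whose window *ends* at start + rel_tick
        idx = (start + np.round(rel_ticks / tick_s).astype(int) * hop
               - n_win) // hop
        if idx[-1] >= n_windows or idx[0] < 0:
            logger.info("trial at sample %d incomplete; excluded", start)
            continue
        power = spec[:, idx]    # freq x tick
        bmask = (rel_ticks >= baseline[0]) & (rel_ticks <= baseline[1])
        if not bmask.any():
            logger.info("trial at sample %d has no rest window; excluded",
                        start)
            continue
        ref = power[:, bmask].mean(axis=1)
        if np.any(ref <= 0):
            logger.info("trial at sample %d has degenerate reference; "
                        "excluded", start)
            continue
        per_trial.append(100.0 * (power - ref[:, None]) / ref[:, None])

    if not per_trial:
        raise ValueError("no complete trial with a valid rest baseline")
    stack = np.asarray(per_trial)
    return ERSPMap(
        freqs=freqs,
        times=rel_ticks[:n_ticks],
        values=stack.mean(axis=0),
        n_trials=len(per_trial),
        baseline_window=baseline,
        trial_values=stack if keep_trials else None,
    )


def block_average_ersp(
    ersp_map: ERSPMap,
    window: tuple[float, float] = (6.0, 12.0),
    foi: float = 10.0,
) -> float:
    """Mean ERSP at the frequency of interest over a trial-time window."""
    fi = int(np.argmin(np.abs(ersp_map.freqs - foi)))
    tmask = (ersp_map.times >= window[0]) & (ersp_map.times <= window[1])
    if not tmask.any():
        raise ValueError("window outside the trial time axis")
    return float(ersp_map.values[fi, tmask].mean())
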