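"""Synthetic EEG, SEP and behavioral data with known ground truth.

Every downstream stage of the pipeline (closed-loop replay, spectral
parameterization, evoked-potential quantification, speed-accuracy fitting,
group statistics) is testable by parameter recovery against the quantities
configured here.

Signal model
------------
EEG channels are a sum of three independent parts:

* an aperiodic 1/f background, constructed in the frequency domain so the
  one-sided PSD is exactly ``10**offset / f**exponent`` (uV^2/Hz),
* a periodic alpha oscillator at the individual alpha frequency (IAF):
  an amplitude-modulated sinusoid with a fresh random phase each trial,
  projected with unit gain on the center channel (C3) and attenuated gain
  on its Laplacian neighbors. During the task period of each trial its
  power is multiplied by ``1 - erd_depth`` (event-related
  desynchronization), with a short linear amplitude ramp at the task
  on/offset to avoid step discontinuities,
* white sensor noise of standard deviation ``noise_sd``.

SEP montages carry stereotyped negative-going Gaussian deflections at the
configured component latencies, superimposed on white noise. Behavioral
outcomes are Bernoulli draws whose success probability follows the
exponential speed-accuracy trade-off ``p(x) = a*exp(-b*x) + c`` over the
time-limit conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import select_word_lengths
from .recordings import EEGRecording, SEPRecording

#: next-nearest neighbors of C3 in the extended 10-20 layout, used by the
#: large-Laplacian spatial filter
DEFAULT_NEIGHBORS = ("F3", "P3", "T7", "Cz")

#: seconds per trial period (rest -> ready -> task -> blank; 17 s total)
DEFAULT_TRIAL_TIMING = {"rest": 5.0, "ready": 1.0, "task": 6.0, "blank": 5.0}


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@dataclass
class EEGSimConfig:
    """Ground-truth parameters of a simulated motor-imagery EEG session.

    ``aperiodic_offset`` is log10 power at 1 Hz (uV^2/Hz); set it to
    ``-inf`` for a background-free (purely oscillatory) signal.
    ``erd_depth`` is the fractional alpha-power attenuation during the
    task period, in [0, 1].
    """

    sampling_rate: float = 1000.0
    n_trials: int = 20
    trial_timing: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRIAL_TIMING)
    )
    channel_set: tuple[str, ...] = ("C3",) + DEFAULT_NEIGHBORS
    center_channel: str = "C3"
    neighbor_channels: tuple[str, ...] = DEFAULT_NEIGHBORS
    iaf_true: float = 10.0
    alpha_amplitude: float = 30.0      # uV, sinusoid amplitude at C3
    neighbor_gain: float = 0.25        # alpha gain on Laplacian neighbors
    erd_depth: float = 0.3
    erd_ramp: float = 0.2              # s, linear amplitude ramp at task edges
    aperiodic_offset: float = 2.0      # log10(uV^2/Hz) at 1 Hz
    aperiodic_exponent: float = 1.5
    noise_sd: float = 1.0              # uV white sensor noise
    seed: int = 0

    @property
    def trial_seconds(self) -> float:
        return float(sum(self.trial_timing.values()))

    def validate(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        missing = [
            ch
            for ch in (self.center_channel, *self.neighbor_channels)
            if ch not in self.channel_set
        ]
        if missing:
            raise ValueError(
                f"channel_set is missing required channels: {missing}"
            )
        if not 8.0 <= self.iaf_true <= 13.0:
            raise ValueError("iaf_true must lie in the alpha band [8, 13] Hz")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")


@dataclass
class SEPComponentSpec:
    """One evoked component: a negative Gaussian deflection on a montage."""

    name: str
    montage: str
    latency_ms: float
    amplitude: float   # uV, depth of the negative deflection (positive number)
    width_ms: float    # Gaussian sigma


DEFAULT_SEP_COMPONENTS = (
    SEPComponentSpec("N9", "EPi-EPc", 9.0, 5.0, 1.5),
    SEPComponentSpec("N13", "C2S-Fz", 13.0, 5.0, 2.0),
    SEPComponentSpec("N20", "CPc-Fz", 20.0, 5.0, 2.5),
)


@dataclass
class SEPSimConfig:
    sampling_rate: float = 10000.0
    n_stimuli: int = 1000
    stim_rate: float = 2.0             # Hz
    component_spec: tuple[SEPComponentSpec, ...] = DEFAULT_SEP_COMPONENTS
    noise_sd: float = 10.0             # uV
    seed: int = 0

    def validate(self) -> None:
        isi_ms = 1000.0 / self.stim_rate
        for comp in self.component_spec:
            if not 0.0 < comp.latency_ms < 300.0:
                raise ValueError(
                    f"{comp.name}: latency must be in (0, 300) ms"
                )
            # template effectively zero beyond 5 sigma; it must die out
            # before the next stimulus arrives
            if comp.latency_ms + 5.0 * comp.width_ms >= isi_ms:
                raise ValueError(
                    f"{comp.name}: template overlaps the next stimulus "
                    f"(latency {comp.latency_ms} ms + 5*width "
                    f"{comp.width_ms} ms >= ISI {isi_ms} ms)"
                )
        if self.n_stimuli < 1:
            raise ValueError("need at least one stimulus")


@dataclass
class BehaviorSimConfig:
    a_true: float = 0.9
    b_true: float = 0.8                # 1/s, saturation speed
    c_true: float = 0.05
    conditions: tuple[float, ...] = (2.0, 4.0, 6.0)
    n_blocks: int = 5
    words_per_block: int = 30
    cpm: float = 150.0                 # typing speed, characters per minute
    seed: int = 0

    def p_success(self, x: float | np.ndarray) -> np.ndarray:
        return self.a_true * np.exp(-self.b_true * np.asarray(x, float)) + self.c_true

    def validate(self) -> None:
        p = self.p_success(np.asarray(self.conditions))
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError(
                "a*exp(-b*x)+c must be a probability at every condition; "
                f"got {p}"
            )
        if self.words_per_block % len(self.conditions):
            raise ValueError(
                "words_per_block must be divisible by the number of "
                "conditions for balanced blocks"
            )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _aperiodic_noise(
    n_samples: int,
    sampling_rate: float,
    offset: float,
    exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise whose one-sided PSD is 10**offset / f**exponent."""
    if np.isneginf(offset):
        return np.zeros(n_samples)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    psd = np.zeros_like(freqs)
    psd[1:] = 10.0 ** offset / freqs[1:] ** exponent
    # complex spectral coefficients scaled so the expected periodogram
    # matches the target density: |A_k|^2 * 2 / (fs * N) = S(f_k)
    scale = np.sqrt(psd * sampling_rate * n_samples / 2.0)
    coeffs = (
        rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    ) / np.sqrt(2.0)
    coeffs *= scale
    coeffs[0] = 0.0
    if n_samples % 2 == 0:
        coeffs[-1] = coeffs[-1].real * np.sqrt(2.0)
    return np.fft.irfft(coeffs, n=n_samples)


def _alpha_envelope(config: EEGSimConfig) -> np.ndarray:
    """Per-trial amplitude envelope implementing the task-period ERD."""
    fs = config.sampling_rate
    timing = config.trial_timing
    n_trial = round(config.trial_seconds * fs)
    env = np.ones(n_trial)
    task_start = round((timing["rest"] + timing["ready"]) * fs)
    task_end = task_start + round(timing["task"] * fs)
    depth_amp = np.sqrt(1.0 - config.erd_depth)   # power -> amplitude
    n_ramp = round(config.erd_ramp * fs)
    env[task_start:task_end] = depth_amp
    if n_ramp > 0:
        down = np.linspace(1.0, depth_amp, n_ramp)
        env[task_start:task_start + n_ramp] = down[: max(0, task_end - task_start)][:n_ramp]
        up_start = task_end
        up = np.linspace(depth_amp, 1.0, n_ramp)
        env[up_start:up_start + n_ramp] = up[: max(0, n_trial - up_start)]
    return env


def generate_eeg_session(config: EEGSimConfig) -> EEGRecording:
    """Simulate one motor-imagery session (n_trials x 17 s, multichannel).

    The alpha oscillator rides on every configured channel with gain 1 on
    the center channel and ``neighbor_gain`` on the Laplacian neighbors;
    all other channels carry background and noise only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_trial = round(config.trial_seconds * fs)
    n_total = n_trial * config.n_trials
    n_ch = len(config.channel_set)

    envelope = _alpha_envelope(config)
    t_trial = np.arange(n_trial) / fs
    alpha = np.empty(n_total)
    for k in range(config.n_trials):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        alpha[k * n_trial:(k + 1) * n_trial] = (
            config.alpha_amplitude
            * envelope
            * np.sin(2.0 * np.pi * config.iaf_true * t_trial + phase)
        )

    gains = np.zeros(n_ch)
    for i, ch in enumerate(config.channel_set):
        if ch == config.center_channel:
            gains[i] = 1.0
        elif ch in config.neighbor_channels:
            gains[i] = config.neighbor_gain

    signal = np.empty((n_ch, n_total))
    for i in range(n_ch):
        background = _aperiodic_noise(
            n_total, fs, config.aperiodic_offset,
            config.aperiodic_exponent, rng,
        )
        white = (
            rng.standard_normal(n_total) * config.noise_sd
            if config.noise_sd > 0
            else 0.0
        )
        signal[i] = gains[i] * alpha + background + white

    rows = []
    timing = config.trial_timing
    for k in range(config.n_trials):
        start = k * n_trial
        offset = 0.0
        for label in ("rest", "ready", "task", "blank"):
            rows.append((start + round(offset * fs), label))
            offset += timing[label]
    events = pd.DataFrame(rows, columns=["onset_sample", "label"])
    return EEGRecording(signal, fs, list(config.channel_set), events)


def sep_template(
    comp: SEPComponentSpec, sampling_rate: float, n_samples: int
) -> np.ndarray:
    """Single-stimulus montage response.

    A Gaussian-windowed negative deflection with compensatory positive
    side lobes (a Ricker shape): the extremum is exactly ``-amplitude``
    at the configured latency, and the zero net area mimics the
    biphasic recovery of real evoked components — a repeated net-area
    deflection would otherwise leave stimulus-locked baseline ripple
    after high-pass filtering.
    """
    t_ms = np.arange(n_samples) / sampling_rate * 1000.0
    x = (t_ms - comp.latency_ms) / comp.width_ms
    return -comp.amplitude * (1.0 - x**2) * np.exp(-0.5 * x**2)


def generate_sep_session(config: SEPSimConfig) -> SEPRecording:
    """Simulate a median-nerve stimulation session on three montages."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    isi = round(fs / config.stim_rate)
    pre_roll = round(0.5 * fs)
    n_total = pre_roll + (config.n_stimuli - 1) * isi + isi  # 0.5 s tail
    onsets = pre_roll + np.arange(config.n_stimuli) * isi

    montages = [c.montage for c in config.component_spec]
    traces = np.empty((len(montages), n_total))
    template_len = isi  # template support: one inter-stimulus interval
    for i, comp in enumerate(config.component_spec):
        tpl = sep_template(comp, fs, template_len)
        trace = (
            rng.standard_normal(n_total) * config.noise_sd
            if config.noise_sd > 0
            else np.zeros(n_total)
        )
        for onset in onsets:
            trace[onset:onset + template_len] += tpl
        traces[i] = trace
    return SEPRecording(traces, fs, montages, onsets)


def generate_behavior(config: BehaviorSimConfig) -> pd.DataFrame:
    """Simulate the touch-typing task.

    Returns one row per word trial with columns ``block``, ``condition_s``,
    ``word_length`` and ``success``. Conditions are balanced within each
    block and presented in pseudo-randomized order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    per_cond = config.words_per_block // len(config.conditions)
    rows = []
    for block in range(1, config.n_blocks + 1):
        order = np.repeat(config.conditions, per_cond)
        rng.shuffle(order)
        for x in order:
            lo, hi = select_word_lengths(config.cpm, x)
            length = int(rng.integers(lo, hi + 1))
            p = float(config.p_success(x))
            rows.append((block, float(x), length, int(rng.random() < p)))
    return pd.DataFrame(
        rows, columns=["block", "condition_s", "word_length", "success"]
    )


# ---------------------------------------------------------------------------
# paired-group (pre/post x verum/sham) datasets
# ---------------------------------------------------------------------------

@dataclass
class GroupEffectSpec:
    """Group-specific pre-to-post deltas for the three study endpoints.

    A "verum-only" training effect is expressed as non-zero
    ``*_delta_verum`` with zero ``*_delta_sham``. ``*_subject_sd`` are
    between-subject standard deviations of the pre-training values.
    """

    erd_pre: float = 0.25
    erd_delta_verum: float = 0.0
    erd_delta_sham: float = 0.0
    erd_subject_sd: float = 0.04

    n20_amp_pre: float = 4.0           # uV
    n20_delta_verum: float = 0.0
    n20_delta_sham: float = 0.0
    n20_subject_sd: float = 0.4

    b_pre: float = 0.6                 # 1/s
    b_delta_verum: float = 0.0
    b_delta_sham: float = 0.0
    b_subject_sd: float = 0.08
    # amplitude/asymptote of the trade-off curve for group sessions: a
    # full ceiling and no guessing floor keep the rate parameter b
    # identifiable from the protocol's three time-limit conditions
    a_true: float = 1.0
    c_true: float = 0.0


@dataclass
class SubjectSession:
    """Seeded generator configs for one subject at one evaluation."""

    eeg: EEGSimConfig
    sep: SEPSimConfig
    behavior: BehaviorSimConfig

    def generate(self) -> tuple[EEGRecording, SEPRecording, pd.DataFrame]:
        return (
            generate_eeg_session(self.eeg),
            generate_sep_session(self.sep),
            generate_behavior(self.behavior),
        )


@dataclass
class SubjectRecord:
    subject: int
    group: str                          # "verum" | "sham"
    sessions: dict[int, SubjectSession]  # evaluation 1 and 2


def generate_group_dataset(
    n_per_group: int,
    effect_spec: GroupEffectSpec,
    seed: int,
    eeg_trials: int = 10,
    sep_stimuli: int = 300,
) -> list[SubjectRecord]:
    """Paired pre/post sessions for a verum and a sham group.

    The returned records hold fully seeded simulator configs (sessions are
    materialized on demand via :meth:`SubjectSession.generate`), so the
    dataset is lightweight and bit-identical under regeneration. Session
    sizes default to a scaled-down protocol (10 trials, 300 stimuli) to
    keep end-to-end group analyses fast; pass ``eeg_trials``/
    ``sep_stimuli`` to restore the full protocol.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    records = []
    subject = 0
    for group in ("verum", "sham"):
        if group == "verum":
            deltas = (
                effect_spec.erd_delta_verum,
                effect_spec.n20_delta_verum,
                effect_spec.b_delta_verum,
            )
        else:
            deltas = (
                effect_spec.erd_delta_sham,
                effect_spec.n20_delta_sham,
                effect_spec.b_delta_sham,
            )
        for _ in range(n_per_group):
            subject += 1
            erd0 = float(np.clip(
                effect_spec.erd_pre
                + rng.normal(0.0, effect_spec.erd_subject_sd), 0.0, 0.95,
            ))
            n20_0 = max(
                0.5,
                effect_spec.n20_amp_pre
                + rng.normal(0.0, effect_spec.n20_subject_sd),
            )
            b0 = max(
                0.05,
                effect_spec.b_pre + rng.normal(0.0, effect_spec.b_subject_sd),
            )
            sessions = {}
            for evaluation, (d_erd, d_n20, d_b) in zip(
                (1, 2), ((0.0, 0.0, 0.0), deltas)
            ):
                sess_seed = int(rng.integers(0, 2**31 - 1))
                comps = tuple(
                    replace(c, amplitude=n20_0 + d_n20)
                    if c.name == "N20"
                    else c
                    for c in DEFAULT_SEP_COMPONENTS
                )
                sessions[evaluation] = SubjectSession(
                    eeg=EEGSimConfig(
                        n_trials=eeg_trials,
                        erd_depth=float(np.clip(erd0 + d_erd, 0.0, 0.95)),
                        seed=sess_seed,
                    ),
                    sep=SEPSimConfig(
                        n_stimuli=sep_stimuli,
                        component_spec=comps,
                        seed=sess_seed + 1,
                    ),
                    behavior=BehaviorSimConfig(
                        a_true=effect_spec.a_true,
                        c_true=effect_spec.c_true,
                        b_true=max(0.05, b0 + d_b),
                        seed=sess_seed + 2,
                    ),
                )
            records.append(SubjectRecord(subject, group, sessions))
    return records
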