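# Methods

`smrloop` re-implements, as a tested library, the computation chain of a
closed-loop sensorimotor-rhythm (SMR) neurofeedback experiment and its
offline analyses. This note documents the models, the tunable parameters
that matter, the synthetic-data generator the tests rely on, and the
design choices made where the design was genuinely open.

## The online feedback model

Every 100 ms the latest 5 s of the large-Laplacian C3 derivation
(C3 minus the mean of its next-nearest 10-20 neighbors F3, P3, T7, Cz)
are band-pass filtered (third-order Butterworth, 3–70 Hz) and notch
filtered (50 ± 2 Hz), both applied forward–backward so the net response
is zero-phase. The final 1 s is Hanning-windowed and Fourier
transformed, giving band power at 1 Hz resolution. Spectral-power
modulation is expressed as the event-related spectral perturbation

    ERSP(f, t) = 100 · (Power(f, t) − Reference(f)) / Reference(f)   [%]

where `Reference(f)` is the mean power over the current trial's 5-s rest
period — a *within-trial* normalization, recomputed for every trial.
The SMR value is either the 8–13 Hz mean ERSP (pre-calibration) or the
single calibrated frequency-of-interest (FOI) bin; the FOI is the
integer alpha bin with the deepest trial-averaged task-period ERSP in an
open-loop calibration block (ties break to the lowest frequency, and a
spectrum with no negative bin still returns the argmin, with a warning).
Raw SMR values are smoothed by a moving average over the latest 10
samples, then mapped affinely onto a 20-frame virtual finger: the 25th
percentile of the calibration block's smoothed-SMR distribution (deep
desynchronization) shows the fully abducted finger (frame 20), the 75th
percentile frame 1, with round-half-up in between and clipping outside.
Both the interpolation rule and the rounding are parameters; only the
two anchor percentiles are fixed by the protocol.

Replay-specific decisions:

* **Rest ticks** are those whose full 1-s analysis window lies inside
  the rest period, so no ready/task signal leaks into the reference.
* **Causality**: a tick at time *t* sees samples up to *t* only;
  truncating a recording does not change earlier ticks (tested).
* **Cold start**: a causal replay of a recording that begins at trial 1
  gives the first trial only one complete rest window. A reference
  averaged from fewer than `min_ref_windows` (default 5) windows is
  treated as degenerate and those ticks are reported as NaN with a log
  entry. A streaming system never enters this state; the choice only
  affects the first trial of an isolated recording.

## Offline spectral analysis

PSDs come from Welch's method (Hanning, 1-s segments by default, 50%
overlap, density scaling; 2-s segments for parameterization, giving
0.5 Hz resolution). The spectrum is parameterized as

    log10 PSD(f) = offset − exponent · log10 f + Σ_k h_k exp(−(f−c_k)²/2σ_k²)

by (1) a robust line fit on log–log axes that iteratively refits on the
points at or below the median residual, so periodic peaks do not drag
the aperiodic component; (2) iterative extraction of Gaussian peaks from
the flattened spectrum (largest residual first, stopping below
`min_peak_height` = 0.05 log-units or 2 residual SDs, at most 6 peaks,
σ constrained to bandwidth 0.5–8 Hz); (3) a joint Gaussian refit and a
final aperiodic refit on the peak-subtracted spectrum. The individual
alpha frequency (IAF) is the center of the highest peak inside 8–13 Hz;
a spectrum without one raises an explicit no-alpha-peak error so the
caller chooses the fallback. The parameterization is scale-equivariant:
scaling the PSD by k shifts the offset by log10 k and changes nothing
else (tested to 1e-10).

Time–frequency ERSP maps use the identical 1-s Hanning STFT at 0.1-s
hops. Offline, the whole record is zero-phase filtered once — the
stationary equivalent of per-buffer forward–backward filtering — and
each trial is normalized by its own rest-period mean before averaging
across trials; trials without a usable rest baseline are excluded with a
log entry. Source estimation is out of scope: the analysis operates on
the Laplacian channel, or on any user-supplied regional time series via
the `signal` argument.

## SEP quantification

Evoked-potential traces (10 kHz) are band-limited to 3–500 Hz
(zero-phase, 4th-order Butterworth sections), epoched into 600-ms
windows centered on each stimulus onset (onsets without a full ±300 ms
window are dropped and logged), averaged across epochs, and z-scored
using the mean and SD of the *averaged* trace's pre-stimulus (−300–0 ms)
segment — the z-after-averaging order is the default; per-epoch
z-scoring is available via the building blocks. Components are the most
negative values within ±3 ms of their nominal latencies (N9 at 9 ms on
EPi−EPc, N13 at 13 ms on C2S−Fz, N20 at 20 ms on CPc−Fz; all
configurable), ties breaking to the earlier latency. Missing montages
yield a partial result with a warning.

## Behavioral model

Success on a word trial is Bernoulli with probability
`y(x) = a·exp(−b·x) + c` of the time limit x ∈ {2, 4, 6} s; `b` (1/s) is
the saturation speed. Fits are nonlinear least squares on pooled
per-condition success rates with bounds a ∈ [0, 1.5], b ∈ [0, 10],
c ∈ [0, 1] and a multi-start over b ∈ {0.1, 0.5, 1, 2}; with three
points the fit interpolates whenever the data admit a valid
parameterization, so the multi-start mainly guards against local minima
in the noisy case. Word-length selection implements the 80–100 %-of-
capacity rule, capacity = cpm/60 × time limit, clamped to at least one
character; an interval emptied by rounding collapses to floor(capacity)
with a warning.

## Statistics

The 2 (group, between) × 2 (time/condition, within) mixed ANOVA uses the
exact two-level decomposition: with subject sums `s_i` and differences
`d_i`, the between part is a one-way ANOVA on subject means and the
within part tests the mean and the group contrast of `d_i`; every effect
has (1, N−2) degrees of freedom, unequal group sizes are handled by the
weighted (observation-level) sums of squares, and the result matches
pingouin to better than 1e-8 (tested on random balanced and unbalanced
designs). Both classical η² (SS_effect/SS_total — the convention shown
by default) and partial η² are reported. The aligned-rank-transform
variant aligns each effect by cell-mean estimates, mid-ranks the aligned
values, and reruns the same ANOVA, one alignment per effect.

The t-test family reports Cohen's d with the pooled SD for two-sample
contrasts and the SD of differences (d_z) for paired/one-sample
contrasts — flagged because conventions differ. The JZS Bayes factor
uses the default Cauchy prior (scale 1/√2) and evaluates the marginal
likelihood ratio by adaptive quadrature over the prior's mixing
parameter; it agrees with an independent implementation to < 1 % and is
returned as log BF10.

Mass-univariate time–frequency testing thresholds the pixelwise t-map at
a two-sided p (default 1e-4), forms 4-connected clusters separately per
sign, uses the cluster *mass* (Σ|t|) as statistic, and builds its null
from ≥1000 sign-flip (one-sample) or label (two-sample) permutations of
the maximum cluster mass. Cluster p-values are Benjamini–Hochberg
corrected; an empty suprathreshold set is a valid (empty) result, not an
error.

## The synthetic-data generator

The generator emulates exactly the statistical structure the analyses
assume, so passing tests demonstrate parameter recovery under the
model's own assumptions — not robustness to real-world artifacts
(eye/muscle activity, electrode drift, non-sinusoidal rhythms, head-model
effects are all absent by design).

* **EEG**: per channel, an aperiodic background built in the frequency
  domain with one-sided PSD exactly `10^offset / f^exponent`
  (defaults offset 2.0 log10(µV²/Hz), exponent 1.5), plus white sensor
  noise (1 µV), plus an alpha sinusoid at the configured IAF with a
  fresh random phase per trial — gain 1 on C3, 0.25 on the Laplacian
  neighbors. During the 6-s task period the alpha *power* is multiplied
  by (1 − erd_depth) with a 200-ms linear amplitude ramp at both task
  edges (no step discontinuities); ready and blank periods carry
  rest-like statistics. The default oscillator amplitude (30 µV peak at
  C3) puts the alpha-bin-to-background ratio near 40 after the
  Laplacian — a strong, clearly resolvable mu rhythm — so that
  single-bin ERD recovery is identifiable at the default 20 trials;
  recovery tolerances would be dominated by background leakage at much
  lower SNR.
* **SEP**: each component is a stereotyped deflection on its own
  montage: a Gaussian-windowed negative main lobe with compensatory
  positive side lobes (Ricker shape) whose extremum is exactly
  −amplitude at the configured latency. The zero net area matters: a
  net-area deflection repeated at exactly 2 Hz leaves stimulus-locked
  baseline ripple after the 3-Hz high-pass, which would break the
  √n averaging-gain property the pipeline is tested against. Defaults:
  5 µV amplitudes, widths 1.5/2.0/2.5 ms, 10 µV white noise (≈3 µV
  within the 3–500 Hz band).
* **Behavior**: balanced pseudo-randomized conditions within each of 5
  blocks of 30 words; defaults (a, b, c) = (0.9, 0.8, 0.05).
* **Group datasets** hold seeded per-session configs (materialized on
  demand, so a 40-session dataset stays lightweight and bit-identical
  under regeneration) with subject-level Gaussian variation around the
  pre-training values and group-specific pre→post deltas. Group
  behavioral sessions use a = 1, c = 0 (every word typeable given
  unlimited time; no guessing floor): with the protocol's three time
  limits and 50 trials per condition, a free floor parameter makes the
  saturation-speed estimate compressed and roughly twice as noisy,
  which would leave the group × time interaction underpowered at any
  realistic sample size. EEG/SEP session sizes default to a
  scaled-down protocol (10 trials, 300 stimuli) for fast end-to-end
  analyses; the full protocol is one argument away.
* The sham arm is modelled only as feedback decoupled from the viewer's
  recording (a replay driven by another recording); no yoked-source
  statistics beyond that are simulated.

## Numerical choices and degenerate inputs

Deterministic seeding throughout (`numpy.random.default_rng`);
regeneration with the same config is bit-identical. Integer-Hz bins
follow from the 1-s analysis window; the alpha band is bins 8–13
inclusive. Round-half-up for frame indices. Zero or negative reference
power, zero pre-stimulus SD, degenerate calibrations (p25 = p75), empty
rest periods and missing channels/montages all raise explicit errors or
warnings rather than propagating NaNs silently. EDF output quantizes to
16 bits over each channel's own physical range; round-trips are exact to
within one quantization step.

## Problem sizes used in the checks

The test-suite and acceptance runs use 20-trial EEG sessions (the
protocol's block length) for recovery checks, 1000-stimulus SEP sessions
with nested 100/400/1000-epoch subsets for the averaging-gain check,
500 Monte-Carlo replicates for the saturation-speed recovery, 5000
simulated nulls for ANOVA type-I calibration, and group datasets of 10
subjects per group (scaled-down sessions) for the end-to-end
interaction checks.

## Known limitations

* The simplified spectral parameterization targets the same model class
  as the published specparam algorithm but is not a re-implementation of
  its exact fitting schedule; agreement is demonstrated by parameter
  recovery on constructed spectra, not against the reference code.
* Channel-level (Laplacian) analysis stands in for cortical source
  estimation; supply source traces via the `signal` hook if available.
* The generator's alpha rhythm is sinusoidal; harmonically rich mu
  rhythms, 1/f knees, and non-stationary noise are not modelled.
* Success/failure is the behavioral observation unit; keystroke timing
  is not simulated.
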