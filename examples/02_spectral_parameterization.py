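"""Parameterize an EEG spectrum into aperiodic and periodic parts.

The session is generated with a known 1/f exponent (1.5) and a known
alpha oscillator at 10.5 Hz; the fit recovers both, plus the modelled
peak height above the aperiodic component.
"""

import smrloop as sl

rec = sl.generate_eeg_session(
    sl.EEGSimConfig(aperiodic_exponent=1.5, iaf_true=10.5, seed=2)
)
lap = sl.large_laplacian(rec)
psd = sl.welch_psd(lap, rec.sampling_rate, segment_s=2.0)
params = sl.parameterize_spectrum(psd)

print(f"aperiodic offset:   {params.aperiodic_offset:.3f} log10(uV^2/Hz)")
print(f"aperiodic exponent: {params.aperiodic_exponent:.3f}  (true: 1.5)")
iaf = sl.find_iaf(params)
print(f"IAF:                {iaf:.2f} Hz  (true: 10.5)")
print(f"peak height at IAF: {sl.peak_height_at_iaf(params):.2f} log10 units")
print(f"model fit R^2:      {params.r_squared:.4f}")
print()
print("The exponent characterizes the broadband 1/f background; the IAF")
print("peak is the periodic sensorimotor alpha rhythm the neurofeedback")
print("loop targets.")
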