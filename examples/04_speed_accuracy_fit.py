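"""Fit the exponential speed-accuracy trade-off to typing outcomes.

Simulates 5 blocks x 30 words of a time-limited touch-typing task whose
success probability follows y = a*exp(-b*x) + c over the time limits
{2, 4, 6} s, then recovers the saturation speed b from the per-condition
success rates.
"""

import smrloop as sl

cfg = sl.BehaviorSimConfig(a_true=0.9, b_true=0.8, c_true=0.05, seed=4)
table = sl.generate_behavior(cfg)
rates = sl.success_rates(table)
fit = sl.fit_sat_curve(rates.index.to_numpy(), rates.to_numpy())

print("success rate per time limit:")
for x, r in rates.items():
    print(f"  {x:.0f} s: {r:.3f}  (true p = {cfg.p_success(x):.3f})")
print(f"fitted a={fit.a:.3f}, b={fit.b:.3f} 1/s, c={fit.c:.3f} "
      f"(true 0.9, 0.8, 0.05)")
print(f"saturation speed: {sl.saturation_speed(fit):.3f} 1/s")
print()
print("b quantifies how quickly accuracy plateaus as the time limit")
print("grows; a larger b after training indicates a resolved")
print("speed-accuracy trade-off.")
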