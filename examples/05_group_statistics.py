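"""End-to-end group analysis: from sessions to interaction tests.

Generates a paired pre/post dataset for a verum and a sham group in
which only the verum group improves (deeper desynchronization, larger
N20, faster saturation speed), extracts the three endpoints per subject
and evaluation by running the full pipeline, and tests each with a
2 (group) x 2 (evaluation) mixed repeated-measures ANOVA.

Takes ~20 s: it analyzes 32 synthetic sessions.
"""

import warnings

warnings.filterwarnings("ignore")

import smrloop as sl                                   # noqa: E402
from smrloop import pipeline                            # noqa: E402

effect = sl.GroupEffectSpec(
    erd_pre=0.25, erd_delta_verum=0.2,
    n20_amp_pre=4.0, n20_delta_verum=1.5,
    b_pre=0.2, b_delta_verum=0.7,
)
records = sl.generate_group_dataset(8, effect, seed=5)
endpoints = pipeline.extract_endpoints(records)
results = pipeline.group_anova(endpoints)

for endpoint, res in results.items():
    row = res.loc["interaction"]
    print(f"{endpoint:6s} group x time interaction: "
          f"F(1,{int(row.df2)}) = {row.F:6.2f}, p = {row.p:.4g}, "
          f"eta^2 = {row.eta_sq:.3f}")
print()
print("All three interactions are significant because the simulated")
print("training effect is confined to the verum group; rerunning with a")
print("zero-effect GroupEffectSpec() leaves them at chance level.")
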