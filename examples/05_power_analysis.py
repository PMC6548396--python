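"""Power analysis via the regression approximation.

Dyadic path models without latent variables are powered through an
equivalent multiple regression: here the study design of 312 dyads and 12
predictors at alpha = .05.
"""

import dyadmed as dm

spec = dm.PowerSpec(n=312, predictors=12, alpha=0.05, f2=0.09)
power = dm.power_ftest(spec)
print(f"power at f2 = 0.09: {power:.3f}  (~{round(100 * power)}%)")

f2 = dm.solve_f2(n=312, predictors=12, alpha=0.05, target_power=0.95)
print(f"smallest effect detectable with 95% power: f2 = {f2:.3f}")
# f2 ~ 0.09 is a small effect (f2 = R2/(1-R2), i.e. R2 ~ 8%): the design is
# sensitive to small omnibus effects.

for n in (100, 200, 312, 500):
    p = dm.power_ftest(dm.PowerSpec(n=n, predictors=12, alpha=0.05, f2=0.09))
    print(f"  n = {n:4d}: power = {p:.3f}")
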