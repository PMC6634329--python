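"""Post-hoc sensitivity analysis via the noncentral t distribution.

Given a sample size, alpha level and target power, what is the smallest
true effect size d a two-sided paired/one-sample t-test could reliably
detect?  Used to bound how large an undetected behavioral effect of the
luminance modulation could have been.
"""

from pupiltag import sensitivity_min_d, t_power

n, alpha = 12, 0.05
for power in (0.80, 0.95):
    d = sensitivity_min_d(n, alpha, power)
    print(f"n = {n}, alpha = {alpha}, power = {power:.2f} "
          f"-> minimum detectable d = {d:.4f} "
          f"(achieved power {t_power(d, n, alpha):.4f})")

print()
print("With 12 subjects, only effects of d >= 0.89 would be detected with")
print("80% probability; null results on smaller behavioral effects are")
print("therefore inconclusive at this sample size.")
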