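"""Simulate one SW-CRT and fit all three treatment-effect models by feasible GLS.

The generator follows the reference study conditions: 18 clusters, 10 periods,
30 individuals per cell, a cluster random intercept (0.1), cluster-period
interaction (1/90), unit residual variance, a linear secular trend, and a
delayed exposure-time effect curve whose true ETATE is 2.83.
"""

from swtime import aggregate_estimands, estimand_contrast, fit_fgls, model_variance
from swtime.simulate import generate_trial, reference_scenario

scenario = reference_scenario("ETI", seed=7)
trial = generate_trial(scenario, rep_index=0)
print(f"simulated {len(trial)} individual outcomes "
      f"({scenario.design.I} clusters x {scenario.design.J} periods x K={scenario.design.K})")
print(f"true ETATE estimand: {scenario.structure.effects.mean():.4f}\n")

for kind in ("IT", "ETI", "CTI"):
    fit = fit_fgls(trial, scenario.design, kind)
    label, estimate = aggregate_estimands(fit)
    rpt = model_variance(fit, estimand_contrast(scenario.design, kind))
    print(f"{kind} model -> {label} = {estimate:+.3f} "
          f"(95% CI {rpt.ci_low:+.3f} to {rpt.ci_high:+.3f}; "
          f"gamma-hat = {fit.gamma_used:.3f})")

print("\nOnly the correctly specified ETI fit recovers the true ETATE; the IT and")
print("CTI analyses, blind to exposure time, land near the sign-reversed values")
print("predicted by the estimand weights.")
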