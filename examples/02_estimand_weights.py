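"""Expose the estimand weights of misspecified SW-CRT estimators.

Every estimator here is linear in the cluster-period means, so its expectation
under a *different* true effect structure is a weighted sum of the true effect
curve.  The weights always sum to 1, but under a nested exchangeable working
correlation (gamma > 0) some can be negative - which is how an estimator can
average below zero even when every true effect is nonnegative.
"""

import numpy as np

from swtime import (
    Design,
    TreatmentStructure,
    expected_estimate,
    numerical_weights,
    w1_closed_form,
)

Q, gamma = 9, 0.69  # 9 sequences, 10 periods; gamma of the reference study
design = Design(I=Q, J=Q + 1, K=30)

print(f"IT estimator weights on true exposure-time effects (Q={Q}, gamma={gamma}):")
w = w1_closed_form(Q, gamma, np.arange(1, Q + 1))
for s, ws in enumerate(w, start=1):
    marker = "  <-- negative" if ws < 0 else ""
    print(f"  delta_{s}: {ws:+.4f}{marker}")
print(f"  sum: {w.sum():.6f}")

# a delayed ramp-up effect curve: zero early, large late
delta = TreatmentStructure("ETI", [0, 0, 0.5, 1, 2, 4, 6, 6, 6])
ew = numerical_weights(design, gamma, "IT", "ETI")
print(f"\ntrue ETATE (mean of delta): {delta.effects.mean():.4f}")
print(f"expected IT estimate:       {expected_estimate(ew, delta):+.4f}")
print("The late (large) effects carry the negative weights, so the misspecified")
print("IT analysis converges to a negative value despite all effects >= 0.")

print("\nIT estimator weights on true calendar-time effects are gamma-free and >= 0:")
for g in (0.0, 0.3, 0.69):
    w2 = numerical_weights(design, g, "IT", "CTI").weights
    print(f"  gamma={g:.2f}: {np.round(w2, 4)}")
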