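"""Replicate study: bias, precision, and coverage of the competing estimators.

Runs a reduced (100-replicate) version of the reference study for the
exposure-time truth and compares the correctly specified ETI analysis with the
misspecified IT analysis, each under nested exchangeable (feasible GLS) and
independence (OLS) working correlations.
"""

from dataclasses import replace

from swtime import AnalysisSpec, estimand_truth, run_study
from swtime.simulate import reference_scenario

scenario = replace(reference_scenario("ETI", seed=1), n_reps=100)
truth = estimand_truth(scenario.structure, scenario.design)
print(f"true ETATE estimand: {truth:.4f}; "
      f"gamma = {scenario.gamma:.3f}; {scenario.n_reps} replicates\n")

out = run_study(
    scenario,
    [
        AnalysisSpec("ETI", "nested_exchangeable", ("model",)),
        AnalysisSpec("ETI", "independence", ("model", "CR2")),
        AnalysisSpec("IT", "nested_exchangeable", ("model",)),
        AnalysisSpec("IT", "independence", ("model",)),
    ],
)
cols = ["estimator", "correlation", "variance", "mean_estimate", "percent_bias",
        "precision", "coverage", "empirical_variance"]
print(out.summary[cols].round(4).to_string(index=False))

print("\nReading the table: the correctly specified ETI analyses are unbiased under")
print("either working correlation; the misspecified IT analysis under nested")
print("exchangeable averages *negative* (percent bias < -100), while under")
print("independence its weights are nonnegative and the bias is far smaller.")
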