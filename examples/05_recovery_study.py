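"""Simulation-based validation: recover known effects through the pipeline.

Generates replicate datasets with known standardized coefficients, runs
the full analysis on each, and summarizes bias, sign agreement and
variable-importance ranking. (The acceptance-grade study uses 300 patches
and 50 replicates; this demo is scaled down to run in seconds.)
"""

from patchmeta import DynamicsConfig, simulate_and_recover
from patchmeta.synthetic import scaled_landscape_config

landscape = scaled_landscape_config(150, n_unsurveyed=25, seed=0)
dynamics = DynamicsConfig(seed=0)  # truth: host +0.85, area +0.6, conn:host -0.7
report = simulate_and_recover(landscape, dynamics, n_replicates=8, seed=3)

summary = report.summary(tolerance=0.2)
cols = ["generation", "column", "truth", "mean_estimate", "mean_bias",
        "sign_correct_rate"]
print(summary.loc[summary["truth"] != 0, cols].round(3).to_string(index=False))
print("\nimportance separation (true terms above all null terms):",
      report.importance_separation_rate())
print("\nSign recovery of the true effects should be essentially perfect; "
      "estimates center on the truth, with the interaction the noisiest "
      "term because connectivity is measured from the surveys themselves.")
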