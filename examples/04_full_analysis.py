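"""Run the full pipeline: responses, connectivity, AICc multimodel inference.

All 194 marginality-respecting candidate models are fitted for each of the
six response x generation analyses, ranked by AICc, and averaged over the
95% cumulative-Akaike-weight confidence set. The coefficient tables report
standardized model-averaged estimates, unconditional SEs, and
sum-of-weights variable importance.
"""

from patchmeta import (AnalysisConfig, DynamicsConfig, LandscapeConfig,
                       run_pipeline, simulate_dataset)

patches, surveys = simulate_dataset(LandscapeConfig(seed=1), DynamicsConfig(seed=1))
result = run_pipeline(patches, surveys, AnalysisConfig())

res = result.analyses[("occupancy", "summer")]
print(f"summer occupancy model: n = {res.n} patches, "
      f"{len(res.averaged.confidence_set)} models in the 95% confidence set")
print(res.averaged.table().round(3).to_string(index=False))
print("\nHost-plant density and patch area carry the largest standardized "
      "effects; the negative connectivity:host interaction means host "
      "density matters most in isolated patches (a rescue effect in "
      "well-connected ones). The synthetic truth behind this dataset is "
      "host +0.85, area +0.6, connectivity:host -0.7.")
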